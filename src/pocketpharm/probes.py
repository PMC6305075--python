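"""Chemical-probe scoring on the pocket lattice.

Five probe types — H-bond donor (HBD), H-bond acceptor (HBA), positive and
negative charge, and hydrophobic — are scored at every pocket grid point
against the complementary receptor atoms. The scoring function is a
transparent surrogate for GRID-style interaction energies: each
complementary atom within a 5 A cutoff contributes a Gaussian well
exp(-(r - r_ideal)^2 / (2 sigma^2)) centered at the ideal contact distance
(2.9 A heavy-to-heavy for H bonds, 3.5 A for charge pairs, vdW contact for
hydrophobic), the contributions are summed and the total clamped to [0, 1].
This keeps scores unit-free and unimodal in distance, so the literature
filter thresholds apply directly on a [0, 1] scale. A grid point clashing
with any receptor heavy atom (closer than 0.7 x the sum of vdW radii,
taking a 1.5 A probe radius) scores zero for every probe. No angular
weighting is applied here: directionality is enforced downstream by the
hybridization-cone projection. The whole function sits behind a single
interface so a different energy model can be swapped in.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from io import StringIO

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .pocket import PocketGrid
from .structure import ProteinStructure, Role

#: Gaussian well width (A).
SIGMA = 0.8
#: Pair cutoff (A).
CUTOFF = 5.0
#: Clash factor: a grid point closer than CLASH_FACTOR * (r_vdw_atom + PROBE_RADIUS)
#: to any heavy atom is considered buried and scores zero.
CLASH_FACTOR = 0.7
PROBE_RADIUS = 1.5
#: Ideal heavy-to-heavy hydrogen-bond distance (A).
HBOND_IDEAL = 2.9
#: Ideal charge-pair distance (A).
CHARGE_IDEAL = 3.5
#: Probe carbon vdW radius for hydrophobic contacts (A).
PROBE_C_VDW = 1.70


class ProbeType(Enum):
    HBD = "HBD"
    HBA = "HBA"
    POS = "POS"
    NEG = "NEG"
    HYDROPHOBIC = "HYDROPHOBIC"


PROBE_ORDER = [ProbeType.HBD, ProbeType.HBA, ProbeType.POS, ProbeType.NEG, ProbeType.HYDROPHOBIC]

#: Receptor role each probe senses. A donor probe is rewarded near receptor
#: acceptors, an acceptor probe near receptor donors, and charges near
#: their opposite sign.
COMPLEMENT_ROLE = {
    ProbeType.HBD: Role.ACCEPTOR,
    ProbeType.HBA: Role.DONOR_HEAVY,
    ProbeType.POS: Role.ANIONIC,
    ProbeType.NEG: Role.CATIONIC,
    ProbeType.HYDROPHOBIC: Role.HYDROPHOBIC,
}


def ideal_distance(probe: ProbeType, atom_vdw: float) -> float:
    """Ideal probe--atom contact distance (A) for one receptor atom."""
    if probe in (ProbeType.HBD, ProbeType.HBA):
        return HBOND_IDEAL
    if probe in (ProbeType.POS, ProbeType.NEG):
        return CHARGE_IDEAL
    if probe is ProbeType.HYDROPHOBIC:
        return atom_vdw + PROBE_C_VDW
    raise ValueError(f"unknown probe type: {probe!r}")


@dataclass
class ProbeMap:
    """Per-grid-point scores for the five probes, columns in PROBE_ORDER."""

    grid: PocketGrid
    scores: np.ndarray

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.grid), len(PROBE_ORDER)):
            raise ValueError("scores must be (n_points, 5)")

    def column(self, probe: ProbeType) -> np.ndarray:
        return self.scores[:, PROBE_ORDER.index(probe)]

    def copy(self) -> "ProbeMap":
        return ProbeMap(grid=self.grid, scores=self.scores.copy())

    def to_csv(self) -> str:
        df = pd.DataFrame(self.grid.points, columns=["x", "y", "z"])
        for i, probe in enumerate(PROBE_ORDER):
            df[probe.value] = self.scores[:, i]
        return df.to_csv(index=False, float_format="%.6f")

    @classmethod
    def from_csv(cls, text: str, spacing: float = 0.5) -> "ProbeMap":
        df = pd.read_csv(StringIO(text))
        grid = PocketGrid(points=df[["x", "y", "z"]].to_numpy(), spacing=spacing)
        scores = df[[p.value for p in PROBE_ORDER]].to_numpy()
        return cls(grid=grid, scores=scores)


def _clash_mask(points: np.ndarray, coords: np.ndarray, vdw: np.ndarray) -> np.ndarray:
    if len(coords) == 0:
        return np.zeros(len(points), dtype=bool)
    d = cdist(points, coords)
    return np.any(d < CLASH_FACTOR * (vdw + PROBE_RADIUS)[None, :], axis=1)


def score_probe(point: np.ndarray, probe: ProbeType, structure: ProteinStructure) -> float:
    """Score one probe at one point; see the module docstring for the form."""
    if probe not in COMPLEMENT_ROLE:
        raise ValueError(f"unknown probe type: {probe!r}")
    point = np.asarray(point, dtype=float).reshape(1, 3)
    coords = structure.coords_array()
    vdw = structure.vdw_array()
    if len(coords) == 0:
        return 0.0
    if _clash_mask(point, coords, vdw)[0]:
        return 0.0
    role = COMPLEMENT_ROLE[probe]
    idx = [i for i, a in enumerate(structure.atoms) if role in a.roles]
    if not idx:
        return 0.0
    d = cdist(point, coords[idx])[0]
    r_ideal = np.array([ideal_distance(probe, vdw[i]) for i in idx])
    within = d <= CUTOFF
    total = np.sum(np.exp(-((d[within] - r_ideal[within]) ** 2) / (2.0 * SIGMA**2)))
    return float(min(1.0, total))


def build_probe_map(grid: PocketGrid, structure: ProteinStructure) -> ProbeMap:
    """Score all five probes at every grid point (vectorized)."""
    points = grid.points
    coords = structure.coords_array()
    vdw = structure.vdw_array()
    scores = np.zeros((len(points), len(PROBE_ORDER)))
    if len(coords) == 0:
        return ProbeMap(grid=grid, scores=scores)
    clash = _clash_mask(points, coords, vdw)
    d_all = cdist(points, coords)
    for col, probe in enumerate(PROBE_ORDER):
        role = COMPLEMENT_ROLE[probe]
        idx = [i for i, a in enumerate(structure.atoms) if role in a.roles]
        if not idx:
            continue
        d = d_all[:, idx]
        r_ideal = np.array([ideal_distance(probe, vdw[i]) for i in idx])
        term = np.exp(-((d - r_ideal[None, :]) ** 2) / (2.0 * SIGMA**2))
        term[d > CUTOFF] = 0.0
        scores[:, col] = np.minimum(1.0, term.sum(axis=1))
    scores[clash] = 0.0
    return ProbeMap(grid=grid, scores=scores)
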