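"""Probe-map filtering into representative feature points (pt1).

Three stages, applied per probe type:

1. score thresholding — scores strictly below the type's threshold are
   zeroed (0.15 for the H-bond probes, 0.2 for hydrophobic, 0.5 for the
   charge probes); a score exactly at the threshold survives;
2. same-type neighbor counting — a nonzero point survives only if strictly
   more than the type's threshold count (30/30/40/5/5) of nonzero
   same-type points lie within the neighbor radius;
3. 2.5 A non-maximum suppression — the highest-scoring surviving point is
   emitted as the representative of its region and all same-type points
   within 2.5 A of it are suppressed, repeatedly until none remain. Ties
   are broken by a rigid-motion-invariant spread measure, then coordinates
   and grid index, so output is deterministic and frame-independent.

The emitted representatives form the point set pt1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np
from scipy.spatial import cKDTree

from .probes import ProbeMap, ProbeType, PROBE_ORDER


#: Metric slack for inclusive distance boundaries and score thresholds.
#: Grid points routinely sit exactly at the 2.0/2.5/3.0 A radii (lattice
#: multiples), and a rigid motion perturbs those distances by an ulp; the
#: slack keeps boundary decisions stable under such motions.
EPS_DIST = 1e-9
EPS_SCORE = 1e-12


class FeatureType(Enum):
    HBA = "HBA"
    HBD = "HBD"
    POS = "POS"
    NEG = "NEG"
    HYDROPHOBIC = "HYDROPHOBIC"
    AROMATIC = "AROMATIC"


class Provenance(Enum):
    PT1 = "PT1"
    PT2 = "PT2"
    MERGED = "MERGED"
    AROMATIC = "AROMATIC"


#: Ligand-side feature type produced by each probe.
PROBE_FEATURE = {
    ProbeType.HBD: FeatureType.HBD,
    ProbeType.HBA: FeatureType.HBA,
    ProbeType.POS: FeatureType.POS,
    ProbeType.NEG: FeatureType.NEG,
    ProbeType.HYDROPHOBIC: FeatureType.HYDROPHOBIC,
}


@dataclass
class FilterConfig:
    """Filter and geometry thresholds; defaults are the literature values."""

    score_threshold: dict = field(
        default_factory=lambda: {
            ProbeType.HBD: 0.15,
            ProbeType.HBA: 0.15,
            ProbeType.HYDROPHOBIC: 0.2,
            ProbeType.POS: 0.5,
            ProbeType.NEG: 0.5,
        }
    )
    neighbor_threshold: dict = field(
        default_factory=lambda: {
            ProbeType.HBD: 30,
            ProbeType.HBA: 30,
            ProbeType.HYDROPHOBIC: 40,
            ProbeType.POS: 5,
            ProbeType.NEG: 5,
        }
    )
    #: radius (A) for the same-type neighbor count; ~4 lattice cells at the
    #: default 0.5 A pitch, which makes counts of 30-40 geometrically
    #: attainable inside a well-formed hotspot.
    neighbor_radius: float = 2.0
    representative_radius: float = 2.5
    merge_radius: float = 3.0
    aromatic_search_radius: float = 4.5
    min_aromatic_atoms: int = 6
    aromatic_normal_max_angle: float = 60.0

    def __post_init__(self):
        for r in (self.neighbor_radius, self.representative_radius, self.merge_radius,
                  self.aromatic_search_radius):
            if r <= 0:
                raise ValueError("all radii must be positive")
        if any(v < 0 for v in self.score_threshold.values()):
            raise ValueError("score thresholds must be non-negative")
        if any(v < 0 for v in self.neighbor_threshold.values()):
            raise ValueError("neighbor thresholds must be non-negative")

    def to_dict(self) -> dict:
        return {
            "score_threshold": {p.value: v for p, v in self.score_threshold.items()},
            "neighbor_threshold": {p.value: v for p, v in self.neighbor_threshold.items()},
            "neighbor_radius": self.neighbor_radius,
            "representative_radius": self.representative_radius,
            "merge_radius": self.merge_radius,
            "aromatic_search_radius": self.aromatic_search_radius,
            "min_aromatic_atoms": self.min_aromatic_atoms,
            "aromatic_normal_max_angle": self.aromatic_normal_max_angle,
        }

    def to_ini(self) -> str:
        """Flat 'key = value' serialization, one threshold per line."""
        lines = []
        for p in PROBE_ORDER:
            lines.append(f"score_threshold.{p.value} = {self.score_threshold[p]}")
        for p in PROBE_ORDER:
            lines.append(f"neighbor_threshold.{p.value} = {self.neighbor_threshold[p]}")
        for key in ("neighbor_radius", "representative_radius", "merge_radius",
                    "aromatic_search_radius", "min_aromatic_atoms",
                    "aromatic_normal_max_angle"):
            lines.append(f"{key} = {getattr(self, key)}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_ini(cls, text: str) -> "FilterConfig":
        cfg = cls()
        for lineno, line in enumerate(text.splitlines(), start=1):
            row = line.split("#", 1)[0].strip()
            if not row:
                continue
            if "=" not in row:
                raise ValueError(f"config line {lineno}: expected 'key = value'")
            key, val = (s.strip() for s in row.split("=", 1))
            if key.startswith("score_threshold."):
                cfg.score_threshold[ProbeType(key.split(".", 1)[1])] = float(val)
            elif key.startswith("neighbor_threshold."):
                cfg.neighbor_threshold[ProbeType(key.split(".", 1)[1])] = int(val)
            elif key == "min_aromatic_atoms":
                cfg.min_aromatic_atoms = int(val)
            elif hasattr(cfg, key):
                setattr(cfg, key, float(val))
            else:
                raise ValueError(f"config line {lineno}: unknown key {key!r}")
        return cfg


@dataclass(eq=False)
class FeaturePoint:
    """One pharmacophore feature: a typed point, optionally directed."""

    ftype: FeatureType
    position: np.ndarray
    score: float
    direction: np.ndarray | None = None
    tolerance: float = 1.5
    provenance: Provenance = Provenance.PT1
    source: str | None = None

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError("feature position must be a finite 3-vector")
        if self.score < 0:
            raise ValueError("feature score must be non-negative")
        if self.tolerance <= 0:
            raise ValueError("feature tolerance must be positive")
        if self.direction is not None:
            self.direction = np.asarray(self.direction, dtype=float)
            if abs(np.linalg.norm(self.direction) - 1.0) > 1e-9:
                raise ValueError("feature direction must be unit norm")

    def with_direction(self, direction: np.ndarray, provenance: Provenance) -> "FeaturePoint":
        return replace(self, direction=direction, provenance=provenance)


def threshold_map(pmap: ProbeMap, cfg: FilterConfig) -> ProbeMap:
    """Zero every score strictly below its probe's threshold (stage 1)."""
    out = pmap.copy()
    for col, probe in enumerate(PROBE_ORDER):
        thr = cfg.score_threshold[probe]
        column = out.scores[:, col]
        column[column < thr - EPS_SCORE] = 0.0
    return out


def neighbor_filter(pmap: ProbeMap, cfg: FilterConfig) -> ProbeMap:
    """Keep a nonzero point only if its same-type nonzero neighbor count
    within ``neighbor_radius`` is strictly greater than the threshold
    (stage 2). The point itself is not counted."""
    out = pmap.copy()
    points = pmap.grid.points
    for col, probe in enumerate(PROBE_ORDER):
        thr = cfg.neighbor_threshold[probe]
        nz = np.flatnonzero(out.scores[:, col] > 0)
        if len(nz) == 0:
            continue
        tree = cKDTree(points[nz])
        counts = np.array(
            [len(tree.query_ball_point(points[i], cfg.neighbor_radius + EPS_DIST)) - 1 for i in nz]
        )
        drop = nz[counts <= thr]
        out.scores[drop, col] = 0.0
    return out


def select_representatives(pmap: ProbeMap, cfg: FilterConfig) -> list:
    """Greedy per-type non-maximum suppression at 2.5 A (stage 3).

    Repeatedly emits the surviving point of highest score and suppresses
    all same-type points within the representative radius, until the type
    is exhausted. Ties — frequent on the clamped score plateau — are broken
    by each point's summed distance to all same-type nonzero points, a
    rigid-motion invariant that is generically unique per point; only then
    by coordinates and grid index, so congruent inputs give congruent
    output. Scores and distance sums enter the ordering rounded (1e-9 /
    1e-5) to absorb ulp-level noise from rigid motions. Returns pt1 as
    FeaturePoints ordered by probe type then emission order.
    """
    from scipy.spatial.distance import cdist

    points = pmap.grid.points
    features: list = []
    for col, probe in enumerate(PROBE_ORDER):
        scores = pmap.scores[:, col]
        nz = np.flatnonzero(scores > 0)
        if len(nz) == 0:
            continue
        spread = cdist(points[nz], points[nz]).sum(axis=1)
        spread_of = {int(i): float(spread[k]) for k, i in enumerate(nz)}
        order = sorted(
            nz,
            key=lambda i: (
                -round(scores[i], 9),
                round(spread_of[int(i)], 5),
                points[i, 0],
                points[i, 1],
                points[i, 2],
                i,
            ),
        )
        tree = cKDTree(points[nz])
        pos_in_nz = {int(i): k for k, i in enumerate(nz)}
        suppressed = np.zeros(len(nz), dtype=bool)
        for i in order:
            k = pos_in_nz[int(i)]
            if suppressed[k]:
                continue
            features.append(
                FeaturePoint(
                    ftype=PROBE_FEATURE[probe],
                    position=points[i].copy(),
                    score=float(scores[i]),
                    provenance=Provenance.PT1,
                )
            )
            near = tree.query_ball_point(points[i], cfg.representative_radius + EPS_DIST)
            suppressed[near] = True
    return features


def filter_probe_map(pmap: ProbeMap, cfg: FilterConfig | None = None) -> list:
    """The full pt1 pipeline: threshold, neighbor count, then NMS."""
    cfg = cfg or FilterConfig()
    return select_representatives(neighbor_filter(threshold_map(pmap, cfg), cfg), cfg)
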