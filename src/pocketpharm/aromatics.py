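"""Aromatic-ring feature extraction.

A hydrophobic representative point is upgraded to an aromatic feature when
(1) at least six aromatic atoms lie within 4.5 A of it, and (2) the normal
of the nearby ring points toward the inner side of the pocket rather than
along the pocket wall. "Toward the inner side" is quantified as an angle
of at most 60 deg (configurable) between the ring normal (either sign) and
the vector from the ring centroid to the pocket-grid centroid — the
simplest ligand-free notion of pocket interior. The source hydrophobic
point is kept alongside the aromatic feature: an aromatic site is still a
hydrophobic one.

A histidine ring alone (5 atoms) can never reach the six-atom count; the
tryptophan fused system is stored as its 5- and 6-membered component rings
but all nine of its aromatic atoms count.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .filtering import FeaturePoint, FeatureType, FilterConfig, Provenance
from .pocket import PocketGrid
from .structure import AROMATIC_RING_ATOMS, ProteinStructure, Role

logger = logging.getLogger(__name__)


@dataclass
class Ring:
    member_atoms: list
    centroid: np.ndarray
    normal: np.ndarray
    residue_key: tuple

    @property
    def planarity_rms(self) -> float:
        coords = np.array([a.coords for a in self.member_atoms]) - self.centroid
        return float(np.sqrt(np.mean(np.dot(coords, self.normal) ** 2)))


def _plane_normal(coords: np.ndarray) -> np.ndarray:
    centered = coords - coords.mean(axis=0)
    _, _, vt = np.linalg.svd(centered)
    return vt[2] / np.linalg.norm(vt[2])


def find_rings(structure: ProteinStructure) -> list:
    """Template-based aromatic ring detection (Phe/Tyr 6-ring, His 5-ring,
    Trp 5+6 rings). Residues missing ring atoms are skipped with a warning."""
    rings = []
    for key, atoms in structure.residues.items():
        templates = AROMATIC_RING_ATOMS.get(key[2])
        if not templates:
            continue
        by_name = {a.name: a for a in atoms}
        for names in templates:
            members = [by_name[n] for n in names if n in by_name]
            if len(members) != len(names):
                logger.warning("residue %s missing ring atoms; skipped", key)
                continue
            coords = np.array([a.coords for a in members])
            rings.append(
                Ring(
                    member_atoms=members,
                    centroid=coords.mean(axis=0),
                    normal=_plane_normal(coords),
                    residue_key=key,
                )
            )
    return rings


def count_aromatic_atoms(point: np.ndarray, structure: ProteinStructure, radius: float = 4.5) -> int:
    """Number of aromatic-member atoms within ``radius`` of the point (inclusive)."""
    point = np.asarray(point, dtype=float)
    return sum(
        1
        for a in structure.atoms
        if Role.AROMATIC_MEMBER in a.roles
        and np.linalg.norm(a.coords - point) <= radius
    )


def normal_into_pocket(ring: Ring, pocket: PocketGrid, max_angle: float = 60.0) -> bool:
    """True iff the ring normal (either sign) points within ``max_angle``
    degrees of the ring-centroid-to-pocket-centroid direction."""
    v = pocket.centroid - ring.centroid
    n = np.linalg.norm(v)
    if n < 1e-9:
        return True  # ring centered on the pocket centroid: any normal faces in
    v = v / n
    cosang = abs(float(np.dot(ring.normal, v)))
    return math.degrees(math.acos(np.clip(cosang, -1.0, 1.0))) <= max_angle


def pocket_facing_normal(ring: Ring, pocket: PocketGrid) -> np.ndarray:
    v = pocket.centroid - ring.centroid
    sign = 1.0 if float(np.dot(ring.normal, v)) >= 0 else -1.0
    return sign * ring.normal


def extract_aromatics(
    pt1_hydrophobic: list,
    structure: ProteinStructure,
    pocket: PocketGrid,
    cfg: FilterConfig | None = None,
) -> list:
    """Upgrade qualifying hydrophobic pt1 points to aromatic features.

    For each hydrophobic point: count aromatic atoms within the search
    radius; if the count reaches the minimum, find the nearest ring whose
    centroid is within the same radius and test its normal orientation.
    Emitted aromatic features sit at the hydrophobic point's position and
    carry the pocket-facing ring normal as direction.
    """
    cfg = cfg or FilterConfig()
    rings = find_rings(structure)
    out = []
    for fp in pt1_hydrophobic:
        if fp.ftype is not FeatureType.HYDROPHOBIC:
            continue
        n = count_aromatic_atoms(fp.position, structure, cfg.aromatic_search_radius)
        if n < cfg.min_aromatic_atoms:
            continue
        candidates = [
            (np.linalg.norm(r.centroid - fp.position), i, r)
            for i, r in enumerate(rings)
            if np.linalg.norm(r.centroid - fp.position) <= cfg.aromatic_search_radius
        ]
        if not candidates:
            continue
        _, _, ring = min(candidates, key=lambda t: (t[0], t[1]))
        if not normal_into_pocket(ring, pocket, cfg.aromatic_normal_max_angle):
            continue
        out.append(
            FeaturePoint(
                ftype=FeatureType.AROMATIC,
                position=fp.position.copy(),
                score=fp.score,
                direction=pocket_facing_normal(ring, pocket),
                tolerance=fp.tolerance,
                provenance=Provenance.AROMATIC,
                source=f"ring:{ring.residue_key}",
            )
        )
    return out
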