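"""Hybridization-based projection of complementary interaction sites (pt2).

Every H-bond-capable or charged atom of a pocket residue defines, through
its SP2/SP3 hybridization, a small set of ideal directions along which a
complementary ligand atom would sit. A site is projected (d + e) A along
each direction, where d is the covalent X-H bond length and e the H...X
contact gap. The lateral tolerance of the site is the base radius c of the
interaction cone:

    a^2 = (d + e)^2 + c^2        (slant length)
    tan(A) = c / (d + e)         (apex half-angle)
    tan(C) = c / e               (half-angle at the hydrogen)

With the empirical c = 1.5 A and e = 2.0 A the maximum angle C is 37 deg,
so the D-H...A angle B = 180 deg - C may not fall below 143 deg; sites
violating that bound would correspond to broken hydrogen bonds and are
rejected. Projected sites are kept only if they fall inside the pocket
lattice and do not clash with receptor atoms. The surviving sites form the
candidate point set pt2.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .filtering import FeaturePoint, FeatureType, Provenance
from .pocket import PocketGrid
from .probes import CLASH_FACTOR, PROBE_RADIUS
from .structure import Atom, Hybridization, ProteinStructure, Role

logger = logging.getLogger(__name__)

#: Ligand-side feature type projected from each receptor role: a receptor
#: donor creates an acceptor region for the ligand (H-A), and so on.
ROLE_COMPLEMENT = {
    Role.DONOR_HEAVY: FeatureType.HBA,
    Role.ACCEPTOR: FeatureType.HBD,
    Role.ANIONIC: FeatureType.POS,
    Role.CATIONIC: FeatureType.NEG,
}

#: Deterministic priority when an atom carries several projectable roles.
ROLE_PRIORITY = [Role.ANIONIC, Role.CATIONIC, Role.ACCEPTOR, Role.DONOR_HEAVY]

TETRAHEDRAL_ANGLE = 109.47122063449069  # degrees


@dataclass(frozen=True)
class ConeParams:
    """Interaction-cone geometry; all lengths in A, angles in degrees."""

    c: float = 1.5
    d: float = 1.0
    e: float = 2.0
    a: float = 0.0
    angle_A: float = 0.0
    angle_C: float = 0.0
    angle_B_min: float = 180.0


def cone_geometry(c: float = 1.5, d: float = 1.0, e: float = 2.0) -> ConeParams:
    """Derive slant length and cone angles from (c, d, e).

    c is the cone base radius, d the covalent donor-H bond length and e
    the H-to-partner contact gap. With the defaults, angle_C = 36.87 deg
    (rounding to 37) and angle_B_min = 143.13 deg (rounding to 143).
    """
    if c < 0 or d < 0 or e <= 0:
        raise ValueError("cone parameters must satisfy c >= 0, d >= 0, e > 0")
    a = math.hypot(d + e, c)
    angle_A = math.degrees(math.atan2(c, d + e))
    angle_C = math.degrees(math.atan2(c, e))
    return ConeParams(c=c, d=d, e=e, a=a, angle_A=angle_A, angle_C=angle_C,
                      angle_B_min=180.0 - angle_C)


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError("zero-length vector")
    return v / n


def _perp_frame(b: np.ndarray) -> tuple:
    """Deterministic orthonormal pair perpendicular to unit vector b."""
    axis = np.zeros(3)
    axis[int(np.argmin(np.abs(b)))] = 1.0
    p0 = _unit(np.cross(b, axis))
    return p0, np.cross(b, p0)


def heavy_neighbors(atom: Atom, structure: ProteinStructure) -> list:
    """Bonded heavy atoms resolved by distance (<1.8 A, <2.0 A when S is involved)."""
    out = []
    for other in structure.atoms:
        if other is atom:
            continue
        cutoff = 2.0 if "S" in (atom.element, other.element) else 1.8
        if np.linalg.norm(atom.coords - other.coords) < cutoff:
            out.append(other)
    return out


def ideal_directions(atom: Atom, structure: ProteinStructure, n_sp3_samples: int = 3) -> list:
    """Unit vectors along which the atom's implicit H atoms / lone pairs point.

    SP2 with two heavy neighbors -> the single in-plane direction bisecting
    the exterior angle. SP2 with one heavy neighbor (e.g. a carbonyl O) ->
    two in-plane directions at 60 deg either side of the bond extension
    (i.e. 120 deg from the bond itself, trigonal lone-pair geometry). SP3
    with one heavy neighbor (hydroxyl O, ammonium N) -> a fan of
    ``n_sp3_samples`` directions on the tetrahedral cone about the bond
    axis (109.5 deg from the bond vector). SP3 with two neighbors -> the
    two remaining tetrahedral directions. Saturated atoms yield nothing.
    """
    nbrs = heavy_neighbors(atom, structure)
    if not nbrs:
        logger.warning("atom %s %s has no resolvable heavy neighbors", atom.serial, atom.name)
        return []
    hyb = atom.hybridization
    units = [_unit(n.coords - atom.coords) for n in nbrs]
    if hyb is Hybridization.SP2:
        if len(nbrs) >= 3:
            return []
        if len(nbrs) == 2:
            return [_unit(-(units[0] + units[1]))]
        b = -units[0]  # bond extension, away from the neighbor
        # Plane of the trigonal system from the neighbor's other neighbor.
        ref = None
        for nn in heavy_neighbors(nbrs[0], structure):
            if nn is not atom:
                ref = nn
                break
        if ref is not None:
            in_plane = ref.coords - nbrs[0].coords
            in_plane = in_plane - np.dot(in_plane, b) * b
            if np.linalg.norm(in_plane) > 1e-9:
                p = _unit(in_plane)
            else:
                p = _perp_frame(b)[0]
        else:
            p = _perp_frame(b)[0]
        s, c = math.sin(math.radians(60.0)), math.cos(math.radians(60.0))
        return [_unit(c * b + s * p), _unit(c * b - s * p)]
    if hyb is Hybridization.SP3:
        if len(nbrs) >= 3:
            return []
        if len(nbrs) == 2:
            half = math.radians(TETRAHEDRAL_ANGLE / 2.0)
            bis = _unit(-(units[0] + units[1]))
            perp = _unit(np.cross(units[0], units[1]))
            return [
                _unit(math.cos(half) * bis + math.sin(half) * perp),
                _unit(math.cos(half) * bis - math.sin(half) * perp),
            ]
        b = -units[0]
        half = math.radians(180.0 - TETRAHEDRAL_ANGLE)  # 70.5 deg about the extension
        # Anchor the fan azimuth to the second-shell atom (staggered
        # reference) so the construction is rigid-motion covariant.
        p0 = None
        for nn in heavy_neighbors(nbrs[0], structure):
            if nn is not atom:
                in_plane = nn.coords - nbrs[0].coords
                in_plane = in_plane - np.dot(in_plane, b) * b
                if np.linalg.norm(in_plane) > 1e-9:
                    p0 = _unit(in_plane)
                    break
        if p0 is None:
            p0, p1 = _perp_frame(b)
        else:
            p1 = np.cross(b, p0)
        dirs = []
        for k in range(n_sp3_samples):
            az = 2.0 * math.pi * k / n_sp3_samples
            dirs.append(
                _unit(
                    math.cos(half) * b
                    + math.sin(half) * (math.cos(az) * p0 + math.sin(az) * p1)
                )
            )
        return dirs
    return []


def project_feature(
    atom: Atom,
    direction: np.ndarray,
    cone: ConeParams,
    role: Role | None = None,
) -> FeaturePoint:
    """Place the complementary interaction site (d + e) A along ``direction``.

    The emitted feature type is the ligand-side complement of the atom's
    role; the stored direction points back at the receptor atom and the
    tolerance is the cone base radius c.
    """
    direction = np.asarray(direction, dtype=float)
    if abs(np.linalg.norm(direction) - 1.0) > 1e-6:
        raise ValueError("projection direction must be unit norm")
    if role is None:
        role = next((r for r in ROLE_PRIORITY if r in atom.roles), None)
    if role not in ROLE_COMPLEMENT:
        raise ValueError(f"atom {atom.serial} has no projectable role")
    return FeaturePoint(
        ftype=ROLE_COMPLEMENT[role],
        position=atom.coords + (cone.d + cone.e) * direction,
        score=1.0,
        direction=-direction,
        tolerance=cone.c,
        provenance=Provenance.PT2,
        source=f"{atom.residue_name}{atom.residue_seq}:{atom.name}",
    )


def angle_ok(
    donor: np.ndarray,
    hydrogen_dir: np.ndarray,
    acceptor_site: np.ndarray,
    cone: ConeParams,
) -> bool:
    """True iff the D-H...A angle is at least angle_B_min (inclusive)."""
    donor = np.asarray(donor, dtype=float)
    h = donor + cone.d * np.asarray(hydrogen_dir, dtype=float)
    v1 = donor - h
    v2 = np.asarray(acceptor_site, dtype=float) - h
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    angle = math.degrees(math.acos(np.clip(cosang, -1.0, 1.0)))
    return angle >= cone.angle_B_min - 1e-9


def extract_pt2(
    structure: ProteinStructure,
    pocket: PocketGrid,
    cone: ConeParams | None = None,
) -> list:
    """Project complementary sites from every role-bearing pocket-residue atom.

    A site survives when it (i) lies inside the pocket (within one lattice
    spacing of some grid point), (ii) satisfies the hydrogen-bond angle
    bound for H-bond types, and (iii) does not clash with any receptor
    atom. Ordering is deterministic: residue file order, atom order, role
    priority, direction index.
    """
    cone = cone or cone_geometry()
    residues = structure.residues
    pocket_keys = set()
    for chain, resseq in pocket.pocket_residues:
        for key in residues:
            if key[0] == chain and key[1] == str(resseq):
                pocket_keys.add(key)
    if pocket.pocket_residues and not pocket_keys:
        logger.warning("no pocket residues matched the structure")
    if not pocket.pocket_residues:
        logger.warning("pocket has no residue list; projecting from all residues")
        pocket_keys = set(residues)

    tree = cKDTree(pocket.points)
    coords = structure.coords_array()
    vdw = structure.vdw_array()
    features = []
    for key, atoms in residues.items():
        if key not in pocket_keys:
            continue
        for atom in atoms:
            roles = [r for r in ROLE_PRIORITY if r in atom.roles]
            if not roles:
                continue
            dirs = ideal_directions(atom, structure)
            for role in roles:
                for direction in dirs:
                    fp = project_feature(atom, direction, cone, role=role)
                    # containment in the pocket lattice
                    dist, _ = tree.query(fp.position)
                    if dist > pocket.spacing:
                        continue
                    # H-bond angle bound (trivially met for on-axis sites,
                    # enforced for completeness and for external callers)
                    if fp.ftype in (FeatureType.HBA, FeatureType.HBD):
                        if not angle_ok(atom.coords, direction, fp.position, cone):
                            continue
                    # clash with receptor heavy atoms
                    d = cdist(fp.position[None, :], coords)[0]
                    if np.any(d < CLASH_FACTOR * (vdw + PROBE_RADIUS)):
                        continue
                    features.append(fp)
    return features
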