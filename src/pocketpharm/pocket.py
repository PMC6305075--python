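"""Binding-pocket grids and synthetic pocket fixtures.

A pocket is represented by the two artifacts a cavity-detection program
emits: a lattice of grid points filling the cavity and the list of
residues lining it. :func:`load_pocket_grid` reads these from simple text
files. :func:`make_toy_pocket` builds a fully synthetic pocket — a roughly
spherical cavity ringed by residue fragments whose functional groups face
inward — together with a ground-truth list of the pharmacophore feature
types those fragments should give rise to. It is the package's test
surface: small, deterministic and with known answers.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .structure import (
    Atom,
    ProteinStructure,
    Role,
    VDW_RADII,
    assign_roles,
)

logger = logging.getLogger(__name__)


@dataclass
class PocketGrid:
    """Lattice points (A) filling a cavity plus the residues lining it."""

    points: np.ndarray
    spacing: float
    pocket_residues: list = field(default_factory=list)

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.size == 0 or self.points.shape[1] != 3:
            raise ValueError("a pocket grid needs at least one 3-D point")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("grid points must be finite")
        if self.spacing <= 0:
            raise ValueError("grid spacing must be positive")

    @property
    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)

    def __len__(self):
        return len(self.points)


class GridParseError(ValueError):
    pass


def load_pocket_grid(grid_text: str, residue_text: str = "", spacing: float = 0.5) -> PocketGrid:
    """Load a pocket grid from 'x y z' rows (whitespace or comma separated).

    Lines starting with '#' and blank lines are ignored. The residue file
    holds one 'chain resseq' pair per line. An empty grid is an error — a
    pocket must contain at least one point.
    """
    points = []
    for lineno, line in enumerate(grid_text.splitlines(), start=1):
        row = line.split("#", 1)[0].strip()
        if not row:
            continue
        parts = row.replace(",", " ").split()
        if len(parts) != 3:
            raise GridParseError(f"line {lineno}: expected 3 columns, got {len(parts)}")
        try:
            points.append([float(v) for v in parts])
        except ValueError as exc:
            raise GridParseError(f"line {lineno}: non-numeric value ({exc})") from exc
    if not points:
        raise GridParseError("grid file contains no points")
    residues = []
    for lineno, line in enumerate(residue_text.splitlines(), start=1):
        row = line.split("#", 1)[0].strip()
        if not row:
            continue
        parts = row.replace(",", " ").split()
        if len(parts) < 2:
            raise GridParseError(f"residue line {lineno}: expected 'chain resseq'")
        residues.append((parts[0], parts[1]))
    return PocketGrid(points=np.array(points), spacing=spacing, pocket_residues=residues)


def write_pocket_grid(grid: PocketGrid) -> str:
    lines = ["# pocket grid: x y z (Angstrom)"]
    for p in grid.points:
        lines.append(f"{p[0]:.3f} {p[1]:.3f} {p[2]:.3f}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Toy pocket fixture
# ---------------------------------------------------------------------------

#: Residue fragment templates in a local frame: +z points into the pocket,
#: the functional group sits near the local origin (on the cavity wall) and
#: the scaffold extends to -z (into the protein). Bond lengths are
#: idealized; only lengths < 1.8 A matter for neighbor resolution.
_S60, _C60 = math.sin(math.radians(60)), math.cos(math.radians(60))
_FRAGMENTS = {
    # carboxylate facing in: plants POS (charge complement) and HBD truths
    "ASP": [
        ("CB", (0.0, 0.0, -2.12)),
        ("CG", (0.0, 0.0, -0.60)),
        ("OD1", (1.099, 0.0, -0.004)),
        ("OD2", (-1.099, 0.0, -0.004)),
    ],
    # backbone carbonyl facing in: plants an HBD truth
    "GLY": [
        ("N", (2.046, 0.0, -3.255)),
        ("CA", (1.316, 0.0, -1.990)),
        ("C", (0.0, 0.0, -1.230)),
        ("O", (0.0, 0.0, 0.0)),
    ],
    # ammonium facing in: plants NEG and HBA truths
    "LYS": [
        ("CD", (1.433, 0.0, -1.996)),
        ("CE", (0.0, 0.0, -1.490)),
        ("NZ", (0.0, 0.0, 0.0)),
    ],
    # phenyl ring in the wall plane, normal into the pocket:
    # plants HYDROPHOBIC and AROMATIC truths
    "PHE": [
        ("CB", (-2.706, 0.0, -0.760)),
        ("CG", (-1.390, 0.0, 0.0)),
        ("CD1", (-0.695, 1.204, 0.0)),
        ("CD2", (-0.695, -1.204, 0.0)),
        ("CE1", (0.695, 1.204, 0.0)),
        ("CE2", (0.695, -1.204, 0.0)),
        ("CZ", (1.390, 0.0, 0.0)),
    ],
    # phenyl ring seen edge-on: its normal lies in the wall plane, so it
    # plants HYDROPHOBIC truths but must NOT yield an aromatic feature
    "PHE_EDGE": [
        ("CB", (0.0, 0.0, -2.110)),
        ("CG", (0.0, 0.0, -0.590)),
        ("CD1", (-1.204, 0.0, 0.105)),
        ("CD2", (1.204, 0.0, 0.105)),
        ("CE1", (-1.204, 0.0, 1.495)),
        ("CE2", (1.204, 0.0, 1.495)),
        ("CZ", (0.0, 0.0, 2.190)),
    ],
    # branched aliphatic side chain facing in: plants a HYDROPHOBIC truth
    "LEU": [
        ("CB", (0.0, 0.0, -2.540)),
        ("CG", (0.0, 0.0, -1.000)),
        ("CD1", (1.261, 0.0, -0.116)),
        ("CD2", (-1.261, 0.0, -0.116)),
    ],
}

#: Wall directions (unit vectors from the pocket center) assigned to
#: consecutive planted environments. Deliberately not axis-aligned: a
#: fragment whose mirror plane coincides with a lattice symmetry plane
#: would create exactly tied probe scores, and the tie-break (coordinate
#: order) is frame-dependent.
_WALL_DIRECTIONS = np.array(
    [
        [0.94, 0.23, 0.25],
        [-0.88, 0.37, -0.30],
        [0.15, 0.93, -0.33],
        [-0.20, -0.83, 0.52],
        [0.31, -0.35, -0.88],
        [-0.42, 0.11, 0.90],
    ]
)
_WALL_DIRECTIONS /= np.linalg.norm(_WALL_DIRECTIONS, axis=1, keepdims=True)

DEFAULT_ENVIRONMENTS = ("ASP", "GLY", "LYS", "PHE", "LEU")


@dataclass
class ToyPocketSpec:
    """Parameters of the synthetic pocket fixture.

    environments: residue fragment names to plant (see ``_FRAGMENTS``).
    radius: cavity radius in A (wall anchors sit on this sphere).
    spacing: lattice pitch in A, within [0.3, 1.5].
    seed: drives the (rigid) random orientation of the whole assembly.
    """

    environments: tuple = DEFAULT_ENVIRONMENTS
    radius: float = 6.0
    spacing: float = 0.5
    seed: int = 0


@dataclass
class TruthEntry:
    ftype: str
    position: np.ndarray
    tolerance: float
    source: str


def _rotation_to_z(target: np.ndarray) -> np.ndarray:
    """Rotation matrix mapping local +z onto ``target`` (unit vector)."""
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(z, target)
    c = float(np.dot(z, target))
    if np.linalg.norm(v) < 1e-12:
        return np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    axis = v / np.linalg.norm(v)
    angle = math.acos(np.clip(c, -1, 1))
    return Rotation.from_rotvec(axis * angle).as_matrix()


def _shell_tolerance(probe) -> float:
    """Outer radius of the probe's scoring shell around a single source atom."""
    from . import probes

    r_ideal = probes.ideal_distance(probe, VDW_RADII["C"])
    from .filtering import FilterConfig

    thr = FilterConfig().score_threshold[probe]
    width = probes.SIGMA * math.sqrt(2.0 * math.log(1.0 / thr))
    return r_ideal + width + 0.2


def make_toy_pocket(spec: ToyPocketSpec):
    """Build a synthetic pocket: structure, grid, and planted-feature truth.

    Residue fragments ring a spherical cavity of the requested radius with
    their functional groups on the wall facing the center. The returned
    truth list contains one entry per role-bearing planted atom (and per
    inward-facing ring), giving the ligand-side feature type it should
    produce and the envelope (source position + interaction-shell radius)
    within which the produced feature must lie. The whole assembly is
    rigidly rotated by a seed-derived rotation, so different seeds give
    congruent but differently oriented fixtures; outputs are deterministic
    per seed.
    """
    from . import probes
    from .aromatics import find_rings

    if not spec.environments:
        raise ValueError("toy pocket spec must plant at least one environment")
    if not (0.3 <= spec.spacing <= 1.5):
        raise ValueError("spacing must lie in [0.3, 1.5] A")
    unknown = [e for e in spec.environments if e not in _FRAGMENTS]
    if unknown:
        raise ValueError(f"unknown environments: {unknown}")
    if len(spec.environments) > len(_WALL_DIRECTIONS):
        raise ValueError("at most 6 environments supported")

    rng = np.random.default_rng(spec.seed)
    global_rot = Rotation.random(random_state=rng).as_matrix()

    atoms = []
    residues = []
    serial = 1
    for i, env in enumerate(spec.environments):
        u = _WALL_DIRECTIONS[i]
        rot = _rotation_to_z(-u)  # local +z (inward) -> -u
        anchor = spec.radius * u
        resseq = str(i + 1)
        resname = env.split("_")[0]
        for name, local in _FRAGMENTS[env]:
            pos = anchor + rot @ np.array(local)
            elem = name[0]
            atoms.append(
                Atom(
                    serial=serial,
                    name=name,
                    element=elem,
                    coords=pos,
                    vdw_radius=VDW_RADII.get(elem, 1.70),
                    residue_name=resname,
                    residue_seq=resseq,
                    chain="A",
                )
            )
            serial += 1
        residues.append(("A", resseq))

    structure = ProteinStructure(atoms=atoms)
    assign_roles(structure)

    # lattice filling the cavity
    n = int(math.floor(spec.radius / spec.spacing))
    axis = np.arange(-n, n + 1) * spec.spacing
    gx, gy, gz = np.meshgrid(axis, axis, axis, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    pts = pts[np.linalg.norm(pts, axis=1) <= spec.radius]

    # apply the seed rotation rigidly to atoms and grid
    for atom in structure.atoms:
        atom.coords = global_rot @ atom.coords
    pts = pts @ global_rot.T
    grid = PocketGrid(points=pts, spacing=spec.spacing, pocket_residues=residues)

    centroid = grid.centroid
    truth = []
    role_to_type = {
        Role.ACCEPTOR: ("HBD", probes.ProbeType.HBD),
        Role.DONOR_HEAVY: ("HBA", probes.ProbeType.HBA),
        Role.ANIONIC: ("POS", probes.ProbeType.POS),
        Role.CATIONIC: ("NEG", probes.ProbeType.NEG),
        Role.HYDROPHOBIC: ("HYDROPHOBIC", probes.ProbeType.HYDROPHOBIC),
    }
    for atom in structure.atoms:
        inward = centroid - atom.coords
        nrm = np.linalg.norm(inward)
        inward = inward / nrm if nrm > 1e-9 else np.array([0.0, 0.0, 1.0])
        for role, (ftype, probe) in role_to_type.items():
            if role in atom.roles:
                r_ideal = probes.ideal_distance(probe, atom.vdw_radius)
                truth.append(
                    TruthEntry(
                        ftype=ftype,
                        position=atom.coords + r_ideal * inward,
                        tolerance=_shell_tolerance(probe),
                        source=f"{atom.residue_name}{atom.residue_seq}:{atom.name}",
                    )
                )
    from .aromatics import normal_into_pocket

    for ring in find_rings(structure):
        if not normal_into_pocket(ring, grid):
            continue  # edge-on rings plant no aromatic expectation
        inward = centroid - ring.centroid
        inward = inward / np.linalg.norm(inward)
        r_hyd = probes.ideal_distance(probes.ProbeType.HYDROPHOBIC, VDW_RADII["C"])
        truth.append(
            TruthEntry(
                ftype="AROMATIC",
                position=ring.centroid + r_hyd * inward,
                tolerance=_shell_tolerance(probes.ProbeType.HYDROPHOBIC),
                source=f"ring:{ring.residue_key}",
            )
        )
    return structure, grid, truth
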