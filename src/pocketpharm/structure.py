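"""PDB parsing and per-atom chemistry annotation.

Receptor structures are read from standard fixed-column PDB text into a
light-weight :class:`ProteinStructure`. Each heavy atom is then annotated
with the chemical roles it can play in receptor--ligand recognition
(H-bond donor/acceptor heavy atom, formal charge center, hydrophobic
carbon, aromatic ring member) and an SP2/SP3 hybridization state, using a
residue-template table. Hydrogens are neither required nor used: apo
crystal structures usually lack them, and the downstream cone geometry
generates ideal hydrogen directions analytically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable

import numpy as np

logger = logging.getLogger(__name__)


class Hybridization(Enum):
    SP2 = "SP2"
    SP3 = "SP3"
    NONE = "NONE"


class Role(Enum):
    DONOR_HEAVY = "DONOR_HEAVY"
    ACCEPTOR = "ACCEPTOR"
    CATIONIC = "CATIONIC"
    ANIONIC = "ANIONIC"
    HYDROPHOBIC = "HYDROPHOBIC"
    AROMATIC_MEMBER = "AROMATIC_MEMBER"


# Bondi-style van der Waals radii (A). Only the elements that occur in
# standard amino acids need to be accurate; others fall back to carbon.
VDW_RADII = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
}
DEFAULT_VDW = 1.70


@dataclass
class Atom:
    """One heavy atom of the receptor.

    ``roles`` and ``hybridization`` are filled in by :func:`assign_roles`;
    a freshly parsed atom has no roles and ``Hybridization.NONE``.
    """

    serial: int
    name: str
    element: str
    coords: np.ndarray
    vdw_radius: float
    residue_name: str
    residue_seq: str
    chain: str
    hybridization: Hybridization = Hybridization.NONE
    roles: set = field(default_factory=set)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.serial}: coords must be a finite 3-vector")
        if self.vdw_radius <= 0:
            raise ValueError(f"atom {self.serial}: vdw_radius must be positive")

    @property
    def residue_key(self):
        return (self.chain, self.residue_seq, self.residue_name)


@dataclass
class ProteinStructure:
    """An ordered list of atoms grouped into residues (file order preserved)."""

    atoms: list

    @property
    def residues(self):
        """Mapping (chain, residue_seq, residue_name) -> list of atoms, in file order."""
        out: dict = {}
        for atom in self.atoms:
            out.setdefault(atom.residue_key, []).append(atom)
        return out

    def coords_array(self) -> np.ndarray:
        if not self.atoms:
            return np.zeros((0, 3))
        return np.array([a.coords for a in self.atoms])

    def vdw_array(self) -> np.ndarray:
        return np.array([a.vdw_radius for a in self.atoms])

    def __len__(self):
        return len(self.atoms)


class PDBParseError(ValueError):
    pass


def _element_from_record(line: str, atom_name: str) -> str:
    elem = line[76:78].strip() if len(line) >= 78 else ""
    if elem:
        return elem.capitalize() if len(elem) > 1 else elem.upper()
    # Fall back to the atom-name convention: column 13 blank means the
    # element is the first character of the name (e.g. " CA " is carbon).
    name = atom_name.strip()
    if name[:1].isdigit():
        name = name[1:]
    return name[:1].upper()


def parse_pdb(text: str, keep_water: bool = False, keep_hetatm: bool = False) -> ProteinStructure:
    """Parse ATOM (and optionally HETATM) records from PDB-format text.

    Water (residue HOH/WAT) is dropped by default: the pharmacophore
    extraction deliberately ignores crystallographic water. Alternate
    locations other than blank or 'A' are skipped; insertion codes are
    appended to the residue sequence key. Empty input yields an empty
    structure.
    """
    atoms = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6]
        if rec not in ("ATOM  ", "HETATM"):
            continue
        if len(line) < 54:
            raise PDBParseError(f"line {lineno}: truncated {rec.strip()} record")
        resname = line[17:20].strip()
        if resname in ("HOH", "WAT") and not keep_water:
            continue
        if rec == "HETATM" and not keep_hetatm:
            continue
        altloc = line[16]
        if altloc not in (" ", "A"):
            continue
        try:
            serial = int(line[6:11])
            x = float(line[30:38])
            y = float(line[38:46])
            z = float(line[46:54])
        except ValueError as exc:
            raise PDBParseError(f"line {lineno}: malformed numeric field ({exc})") from exc
        name = line[12:16].strip()
        element = _element_from_record(line, line[12:16])
        if element == "H":
            continue
        icode = line[26].strip() if len(line) > 26 else ""
        resseq = line[22:26].strip() + icode
        atoms.append(
            Atom(
                serial=serial,
                name=name,
                element=element,
                coords=np.array([x, y, z]),
                vdw_radius=VDW_RADII.get(element, DEFAULT_VDW),
                residue_name=resname,
                residue_seq=resseq,
                chain=line[21],
            )
        )
    return ProteinStructure(atoms=atoms)


def write_pdb(structure: ProteinStructure) -> str:
    """Serialize a structure back to fixed-column PDB text (fixture round-trips)."""
    lines = []
    for atom in structure.atoms:
        name = atom.name if len(atom.name) == 4 else f" {atom.name:<3s}"
        resseq = atom.residue_seq
        icode = " "
        if resseq and resseq[-1].isalpha():
            resseq, icode = resseq[:-1], resseq[-1]
        lines.append(
            f"ATOM  {atom.serial:>5d} {name:<4s} {atom.residue_name:<3s} {atom.chain}"
            f"{int(resseq):>4d}{icode}   {atom.coords[0]:8.3f}{atom.coords[1]:8.3f}"
            f"{atom.coords[2]:8.3f}{1.0:6.2f}{0.0:6.2f}          {atom.element:>2s}"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Residue role templates
# ---------------------------------------------------------------------------
# The template maps (residue, atom name) -> (roles, hybridization). The
# backbone rules apply to every standard residue; side-chain entries below
# extend them. Histidine is treated as a neutral donor/acceptor by default;
# `his_cationic=True` additionally marks its ring nitrogens as charged.

_HYDROPHOBIC_SIDECHAINS = {
    "ALA": ["CB"],
    "VAL": ["CB", "CG1", "CG2"],
    "LEU": ["CB", "CG", "CD1", "CD2"],
    "ILE": ["CB", "CG1", "CG2", "CD1"],
    "MET": ["CB", "CG", "CE"],
    "PRO": ["CB", "CG", "CD"],
    "PHE": ["CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"],
    "TRP": ["CB", "CG", "CD1", "CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"],
}

AROMATIC_RING_ATOMS = {
    "PHE": [["CG", "CD1", "CD2", "CE1", "CE2", "CZ"]],
    "TYR": [["CG", "CD1", "CD2", "CE1", "CE2", "CZ"]],
    "HIS": [["CG", "ND1", "CD2", "CE1", "NE2"]],
    "TRP": [["CG", "CD1", "CD2", "NE1", "CE2"], ["CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"]],
}

STANDARD_RESIDUES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

SP2, SP3 = Hybridization.SP2, Hybridization.SP3

# (roles, hybridization) per side-chain atom. Hybridization is listed only
# where a downstream direction construction depends on it.
_SIDECHAIN_TABLE = {
    ("ASP", "OD1"): ({Role.ACCEPTOR, Role.ANIONIC}, SP2),
    ("ASP", "OD2"): ({Role.ACCEPTOR, Role.ANIONIC}, SP2),
    ("GLU", "OE1"): ({Role.ACCEPTOR, Role.ANIONIC}, SP2),
    ("GLU", "OE2"): ({Role.ACCEPTOR, Role.ANIONIC}, SP2),
    ("ASN", "OD1"): ({Role.ACCEPTOR}, SP2),
    ("ASN", "ND2"): ({Role.DONOR_HEAVY}, SP2),
    ("GLN", "OE1"): ({Role.ACCEPTOR}, SP2),
    ("GLN", "NE2"): ({Role.DONOR_HEAVY}, SP2),
    ("SER", "OG"): ({Role.ACCEPTOR, Role.DONOR_HEAVY}, SP3),
    ("THR", "OG1"): ({Role.ACCEPTOR, Role.DONOR_HEAVY}, SP3),
    ("TYR", "OH"): ({Role.ACCEPTOR, Role.DONOR_HEAVY}, SP3),
    ("LYS", "NZ"): ({Role.DONOR_HEAVY, Role.CATIONIC}, SP3),
    ("ARG", "NE"): ({Role.DONOR_HEAVY, Role.CATIONIC}, SP2),
    ("ARG", "CZ"): ({Role.CATIONIC}, SP2),
    ("ARG", "NH1"): ({Role.DONOR_HEAVY, Role.CATIONIC}, SP2),
    ("ARG", "NH2"): ({Role.DONOR_HEAVY, Role.CATIONIC}, SP2),
    ("HIS", "ND1"): ({Role.DONOR_HEAVY, Role.ACCEPTOR}, SP2),
    ("HIS", "NE2"): ({Role.DONOR_HEAVY, Role.ACCEPTOR}, SP2),
    ("TRP", "NE1"): ({Role.DONOR_HEAVY}, SP2),
    ("CYS", "SG"): ({Role.HYDROPHOBIC}, SP3),
}

# SP2 carbons that anchor planar groups (needed for neighbor-plane lookups).
_SP2_CARBONS = {
    ("ASP", "CG"), ("GLU", "CD"), ("ASN", "CG"), ("GLN", "CD"), ("ARG", "CZ"),
}


def assign_roles(structure: ProteinStructure, his_cationic: bool = False) -> ProteinStructure:
    """Annotate every atom with roles and hybridization from the template table.

    Operates in place and returns the same structure. Idempotent: roles are
    recomputed, not accumulated. Atoms of unknown residues keep empty roles
    (a warning is logged once per residue name).
    """
    warned = set()
    for atom in structure.atoms:
        atom.roles = set()
        atom.hybridization = Hybridization.NONE
        res, name = atom.residue_name, atom.name
        if res not in STANDARD_RESIDUES:
            if res not in warned:
                logger.warning("unknown residue %s: atoms left without roles", res)
                warned.add(res)
            continue
        # Backbone rules.
        if name == "N" and res != "PRO":
            atom.roles.add(Role.DONOR_HEAVY)
            atom.hybridization = SP2
        elif name == "O":
            atom.roles.add(Role.ACCEPTOR)
            atom.hybridization = SP2
        elif name == "OXT":
            atom.roles.add(Role.ACCEPTOR)
            atom.hybridization = SP2
        elif name == "C":
            atom.hybridization = SP2
        # Side-chain template.
        entry = _SIDECHAIN_TABLE.get((res, name))
        if entry is not None:
            roles, hyb = entry
            atom.roles |= roles
            atom.hybridization = hyb
        if (res, name) in _SP2_CARBONS:
            atom.hybridization = SP2
        if name in _HYDROPHOBIC_SIDECHAINS.get(res, ()):
            atom.roles.add(Role.HYDROPHOBIC)
        for ring in AROMATIC_RING_ATOMS.get(res, ()):
            if name in ring:
                atom.roles.add(Role.AROMATIC_MEMBER)
                atom.hybridization = SP2
        if his_cationic and res == "HIS" and name in ("ND1", "NE2"):
            atom.roles.add(Role.CATIONIC)
    return structure


def atoms_with_role(structure: ProteinStructure, role: Role) -> Iterable[Atom]:
    return [a for a in structure.atoms if role in a.roles]
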