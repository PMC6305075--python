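"""Deterministic synthetic screening fixtures.

Given a pharmacophore model, actives are generated as copies of the model
feature set, jittered by Gaussian positional noise and placed in a random
rigid frame per ligand; decoys have the same feature count but a permuted
type multiset and positions resampled uniformly inside the model bounding
box, so they lack the model's typed geometry. This mirrors the
active/decoy structure of screening benchmarks at desk scale: decoys are
count-matched, not chemistry-matched. Ligand sets serialize as
pseudo-ligand SDF records — one carbon atom per feature point with the
feature types in a ``FEATURE_TYPES`` property — plus a labels CSV, the
same dialects the screening CLI consumes.

All randomness flows through a single generator seeded once, so the same
seed reproduces the fixture byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .filtering import FeaturePoint, Provenance
from .model import Pharmacophore
from .screening import LigandFeatures


@dataclass
class FixtureBundle:
    actives: list
    decoys: list
    seed: int
    structure: object = None
    grid: object = None
    truth: list = field(default_factory=list)

    @property
    def labels(self) -> pd.DataFrame:
        rows = [(l.ligand_id, 1) for l in self.actives] + [(l.ligand_id, 0) for l in self.decoys]
        return pd.DataFrame(rows, columns=["ligand_id", "is_active"])

    @property
    def ligands(self) -> list:
        return self.actives + self.decoys

    def labels_map(self) -> dict:
        return {l.ligand_id: True for l in self.actives} | {
            l.ligand_id: False for l in self.decoys
        }

    def to_sdf(self) -> str:
        return "".join(pseudo_ligand_sdf(l) for l in self.ligands)

    def write(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        (directory / "ligands.sdf").write_text(self.to_sdf())
        self.labels.to_csv(directory / "labels.csv", index=False)
        if self.structure is not None:
            from .structure import write_pdb

            (directory / "receptor.pdb").write_text(write_pdb(self.structure))
        if self.grid is not None:
            from .pocket import write_pocket_grid

            (directory / "grid.txt").write_text(write_pocket_grid(self.grid))
            with open(directory / "residues.txt", "w") as fh:
                for chain, resseq in self.grid.pocket_residues:
                    fh.write(f"{chain} {resseq}\n")


def pseudo_ligand_sdf(lig: LigandFeatures) -> str:
    """One SDF record whose atoms are the ligand's feature points."""
    from rdkit import Chem
    from rdkit.Geometry import Point3D

    mol = Chem.RWMol()
    conf = Chem.Conformer(len(lig.features))
    for i, fp in enumerate(lig.features):
        mol.AddAtom(Chem.Atom(6))
        conf.SetAtomPosition(i, Point3D(*map(float, fp.position)))
    mol.AddConformer(conf)
    out = mol.GetMol()
    out.SetProp("_Name", lig.ligand_id)
    out.SetProp("FEATURE_TYPES", ",".join(fp.ftype.value for fp in lig.features))
    sio = StringIO()
    writer = Chem.SDWriter(sio)
    writer.SetKekulize(False)
    writer.write(out)
    writer.close()
    return sio.getvalue()


def make_screening_fixture(
    model: Pharmacophore,
    n_active: int = 20,
    n_decoy: int = 100,
    noise_sd: float = 0.3,
    seed: int = 0,
) -> FixtureBundle:
    """Generate matched active/decoy pseudo-ligand sets for a model.

    noise_sd is the per-coordinate Gaussian jitter (A) applied to active
    feature positions before the per-ligand rigid transform; zero noise
    yields exact copies of the model.
    """
    if len(model.features) < 3:
        raise ValueError("screening fixtures need a model with at least 3 features")
    if n_active < 1 or n_decoy < 1:
        raise ValueError("need at least one active and one decoy")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    positions = np.array([f.position for f in model.features])
    types = [f.ftype for f in model.features]
    lo = positions.min(axis=0) - 2.0
    hi = positions.max(axis=0) + 2.0

    def as_ligand(lid, ftypes, pos):
        feats = [
            FeaturePoint(ftype=t, position=p, score=1.0, provenance=Provenance.PT2)
            for t, p in zip(ftypes, pos)
        ]
        return LigandFeatures(ligand_id=lid, features=feats)

    actives = []
    for k in range(n_active):
        jittered = positions + rng.normal(0.0, noise_sd, size=positions.shape)
        rot = Rotation.random(random_state=rng).as_matrix()
        trans = rng.uniform(-10.0, 10.0, size=3)
        actives.append(as_ligand(f"active_{k:03d}", types, jittered @ rot.T + trans))

    decoys = []
    for k in range(n_decoy):
        perm = rng.permutation(len(types))
        shuffled = [types[i] for i in perm]
        pos = rng.uniform(lo, hi, size=positions.shape)
        decoys.append(as_ligand(f"decoy_{k:03d}", shuffled, pos))

    return FixtureBundle(actives=actives, decoys=decoys, seed=seed)
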