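"""Pharmacophore--ligand matching and virtual-screening metrics.

Matching follows the triangle-hashing recipe: all unordered feature
triples of the model are indexed by their type triple and binned side
lengths; each ligand feature triple is looked up in the index (with one
bin of slack per side), every type-consistent correspondence seeds a
three-point rigid least-squares superposition, the alignment is extended
greedily to all features within a distance tolerance and refined by a
final rigid fit on the matched pairs. The fit score is the matched
fraction of *model* features, so a fragment ligand cannot trivially reach
a perfect score. Ligands are treated as rigid single conformers;
multi-conformer input is scored per conformer, keeping the best.

Screens are evaluated with the ROC AUC (exact Mann-Whitney statistic,
ties counted half) and enrichment factors

    EF = (Hits_sampled / N_sampled) x (N_total / Hits_total)

at the 1, 2 and 5 % fractions of the ranked library.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .filtering import FeaturePoint, FeatureType, Provenance
from .model import Pharmacophore

logger = logging.getLogger(__name__)

#: Degenerate-triangle area threshold (A^2): collinear triples are indexed
#: but never used to seed a transform.
MIN_TRIANGLE_AREA = 0.1


@dataclass
class LigandFeatures:
    ligand_id: str
    features: list

    def positions(self) -> np.ndarray:
        return np.array([f.position for f in self.features])

    def __len__(self):
        return len(self.features)


@dataclass
class ScreenResult:
    ligand_id: str
    fit_score: float
    n_matched: int
    rmsd: float
    rotation: np.ndarray | None = None
    translation: np.ndarray | None = None


@dataclass
class EnrichmentReport:
    auc: float
    ef: dict
    n_total: int
    hits_total: int
    per_fraction: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "ef": {str(k): v for k, v in self.ef.items()},
            "n_total": self.n_total,
            "hits_total": self.hits_total,
            "per_fraction": {str(k): v for k, v in self.per_fraction.items()},
        }


# ---------------------------------------------------------------------------
# Ligand feature perception (RDKit)
# ---------------------------------------------------------------------------

_SMARTS = {
    "donor": "[$([N;!H0;v3,v4&+1]),$([O;H1;+0]),$([S;H1;+0]),$([n;H1;+0])]",
    "acceptor": "[$([O;H1;v2;!$(O-N=O)]),$([O;H0;v2]),$([O;-]),$([o;+0]),"
    "$([N;v3;H0;!$(N=*);!$([N;-]);!$(N-a)]),$([n;H0;X2])]",
    "pos": "[$([N;+1]),$([N;H2&+0][C;!$(C=*)]),$(N=C(N)N)]",
    "neg": "[$([O;-]),$([S;-]),$([O;H0]-[C,S,P]=O)]",
}


def perceive_ligand_features(mol, ligand_id: str | None = None) -> LigandFeatures:
    """Perceive ligand-side pharmacophore features from a 3-D RDKit mol.

    Donors and acceptors sit on the heavy atom; charged carboxylate-like
    groups collapse to the midpoint of their equivalent oxygens; aromatic
    rings contribute a centroid feature with the ring normal; connected
    clusters of three or more apolar carbons contribute their centroid as
    a hydrophobic feature.
    """
    from rdkit import Chem

    if mol is None:
        raise ValueError("molecule is None")
    if mol.GetNumConformers() == 0:
        raise ValueError("molecule has no 3-D coordinates")
    conf = mol.GetConformer()
    pos = np.array([[conf.GetAtomPosition(i).x, conf.GetAtomPosition(i).y,
                     conf.GetAtomPosition(i).z] for i in range(mol.GetNumAtoms())])

    feats: list = []

    def add(ftype, position, direction=None):
        feats.append(
            FeaturePoint(ftype=ftype, position=np.asarray(position, dtype=float),
                         score=1.0, direction=direction, provenance=Provenance.PT2)
        )

    def matches(key):
        patt = Chem.MolFromSmarts(_SMARTS[key])
        return sorted({m[0] for m in mol.GetSubstructMatches(patt)})

    for i in matches("donor"):
        add(FeatureType.HBD, pos[i])
    for i in matches("acceptor"):
        add(FeatureType.HBA, pos[i])

    # charged groups: collapse symmetric carboxylate/guanidinium oxygens/Ns
    neg_atoms = matches("neg")
    used = set()
    carbox = Chem.MolFromSmarts("[CX3](=O)[O;H0,-1]")
    for m in mol.GetSubstructMatches(carbox):
        o_idx = [i for i in m if mol.GetAtomWithIdx(i).GetSymbol() == "O"]
        if any(i in neg_atoms for i in o_idx):
            add(FeatureType.NEG, pos[o_idx].mean(axis=0))
            used.update(o_idx)
    for i in neg_atoms:
        if i not in used:
            add(FeatureType.NEG, pos[i])
    for i in matches("pos"):
        add(FeatureType.POS, pos[i])

    # aromatic rings
    ri = mol.GetRingInfo()
    for ring in ri.AtomRings():
        if all(mol.GetAtomWithIdx(i).GetIsAromatic() for i in ring):
            coords = pos[list(ring)]
            centered = coords - coords.mean(axis=0)
            _, _, vt = np.linalg.svd(centered)
            add(FeatureType.AROMATIC, coords.mean(axis=0), direction=vt[2] / np.linalg.norm(vt[2]))

    # hydrophobic clusters: connected apolar carbons, >= 3 atoms
    apolar = set()
    for atom in mol.GetAtoms():
        if atom.GetSymbol() != "C" or atom.GetFormalCharge() != 0:
            continue
        if any(n.GetSymbol() in ("O", "N", "S", "P") for n in atom.GetNeighbors()):
            continue
        apolar.add(atom.GetIdx())
    seen = set()
    for start in sorted(apolar):
        if start in seen:
            continue
        stack, cluster = [start], []
        while stack:
            i = stack.pop()
            if i in seen:
                continue
            seen.add(i)
            cluster.append(i)
            for n in mol.GetAtomWithIdx(i).GetNeighbors():
                if n.GetIdx() in apolar and n.GetIdx() not in seen:
                    stack.append(n.GetIdx())
        if len(cluster) >= 3:
            add(FeatureType.HYDROPHOBIC, pos[sorted(cluster)].mean(axis=0))

    lid = ligand_id
    if lid is None:
        lid = mol.GetProp("_Name") if mol.HasProp("_Name") else "ligand"
    return LigandFeatures(ligand_id=lid, features=feats)


def ligand_features_from_sdf(text: str) -> list:
    """Read ligands from SDF text into LigandFeatures.

    Records carrying a ``FEATURE_TYPES`` property are pseudo-ligands whose
    atoms *are* feature points (one comma-separated type per atom); all
    other records go through RDKit perception.
    """
    from rdkit import Chem

    out = []
    supplier = Chem.SDMolSupplier()
    supplier.SetData(text, removeHs=False, sanitize=False)
    for k, mol in enumerate(supplier):
        if mol is None:
            logger.warning("SDF record %d could not be read; skipped", k)
            continue
        lid = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"mol{k}"
        if mol.HasProp("FEATURE_TYPES"):
            types = mol.GetProp("FEATURE_TYPES").split(",")
            conf = mol.GetConformer()
            feats = [
                FeaturePoint(
                    ftype=FeatureType(t.strip()),
                    position=np.array([conf.GetAtomPosition(i).x, conf.GetAtomPosition(i).y,
                                       conf.GetAtomPosition(i).z]),
                    score=1.0,
                    provenance=Provenance.PT2,
                )
                for i, t in enumerate(types)
            ]
            out.append(LigandFeatures(ligand_id=lid, features=feats))
        else:
            try:
                Chem.SanitizeMol(mol)
            except Exception:
                logger.warning("SDF record %s failed sanitization; skipped", lid)
                continue
            out.append(perceive_ligand_features(mol, ligand_id=lid))
    return out


# ---------------------------------------------------------------------------
# Triangle hashing and rigid matching
# ---------------------------------------------------------------------------


def _triangle_key(types, sides, bin_width):
    """Canonical hash key for a typed triangle.

    Each vertex is keyed by (type name, binned opposite side); vertices are
    sorted lexicographically so congruent triangles hash identically.
    """
    entries = sorted(
        (types[i].value, int(math.floor(sides[i] / bin_width))) for i in range(3)
    )
    return tuple(entries)


@dataclass
class TriangleIndex:
    bin_width: float
    entries: dict
    model: Pharmacophore

    def __len__(self):
        return sum(len(v) for v in self.entries.values())


def triangle_index(model: Pharmacophore, bin_width: float = 0.5) -> TriangleIndex:
    """Index all unordered model feature triples by type and binned sides.

    Side i is the side opposite vertex i. Collinear triples are stored with
    a degenerate flag and never seed a superposition.
    """
    entries: dict = {}
    feats = model.features
    if len(feats) < 3:
        logger.warning("model has %d features; triangle index is empty", len(feats))
        return TriangleIndex(bin_width=bin_width, entries=entries, model=model)
    for i, j, k in itertools.combinations(range(len(feats)), 3):
        idx = (i, j, k)
        p = [feats[t].position for t in idx]
        sides = [
            float(np.linalg.norm(p[1] - p[2])),
            float(np.linalg.norm(p[0] - p[2])),
            float(np.linalg.norm(p[0] - p[1])),
        ]
        area = 0.5 * float(np.linalg.norm(np.cross(p[1] - p[0], p[2] - p[0])))
        key = _triangle_key([feats[t].ftype for t in idx], sides, bin_width)
        entries.setdefault(key, []).append(
            {"indices": idx, "sides": sides, "degenerate": area < MIN_TRIANGLE_AREA}
        )
    return TriangleIndex(bin_width=bin_width, entries=entries, model=model)


def _kabsch(p: np.ndarray, q: np.ndarray):
    """Rigid transform (R, t) minimizing ||R p + t - q||; standard SVD fit."""
    pc, qc = p.mean(axis=0), q.mean(axis=0)
    h = (p - pc).T @ (q - qc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return r, qc - r @ pc


def _greedy_match(model_feats, lig_pos_t, lig_types, tol):
    """One-to-one greedy assignment of transformed ligand features to model
    features, nearest pairs first, same type only, within tol."""
    pairs = []
    for mi, mf in enumerate(model_feats):
        for li in range(len(lig_types)):
            if lig_types[li] is not mf.ftype:
                continue
            d = float(np.linalg.norm(lig_pos_t[li] - mf.position))
            if d <= tol:
                pairs.append((d, mi, li))
    pairs.sort()
    used_m, used_l, matched = set(), set(), []
    for d, mi, li in pairs:
        if mi in used_m or li in used_l:
            continue
        used_m.add(mi)
        used_l.add(li)
        matched.append((mi, li))
    return matched


def match_ligand(index: TriangleIndex, lig: LigandFeatures, tol: float = 1.5) -> ScreenResult:
    """Align a ligand feature set onto the model and score the overlap.

    Every geometry- and type-compatible triple correspondence seeds a
    three-point rigid superposition; the best seed (by matched fraction of
    model features, then RMSD, then enumeration order) wins. A ligand with
    no compatible triple scores zero.
    """
    model_feats = index.model.features
    n_model = len(model_feats)
    best = ScreenResult(ligand_id=lig.ligand_id, fit_score=0.0, n_matched=0, rmsd=float("inf"))
    if n_model < 3 or len(lig) < 3:
        best.rmsd = 0.0
        return best
    lig_pos = lig.positions()
    lig_types = [f.ftype for f in lig.features]
    bw = index.bin_width

    for li, lj, lk in itertools.combinations(range(len(lig)), 3):
        lidx = (li, lj, lk)
        p = [lig_pos[t] for t in lidx]
        sides = [
            float(np.linalg.norm(p[1] - p[2])),
            float(np.linalg.norm(p[0] - p[2])),
            float(np.linalg.norm(p[0] - p[1])),
        ]
        if 0.5 * float(np.linalg.norm(np.cross(p[1] - p[0], p[2] - p[0]))) < MIN_TRIANGLE_AREA:
            continue
        base = [int(math.floor(s / bw)) for s in sides]
        types = [lig_types[t] for t in lidx]
        # neighbor keys: one bin of slack per side
        seen_keys = set()
        candidates = []
        for db in itertools.product((-1, 0, 1), repeat=3):
            key = _triangle_key(types, [(b + o + 0.5) * bw for b, o in zip(base, db)], bw)
            if key in seen_keys:
                continue
            seen_keys.add(key)
            candidates.extend(index.entries.get(key, ()))
        for entry in candidates:
            if entry["degenerate"]:
                continue
            midx = entry["indices"]
            # try every vertex correspondence with matching types and sides
            for perm in itertools.permutations(range(3)):
                if any(lig_types[lidx[perm[v]]] is not model_feats[midx[v]].ftype
                       for v in range(3)):
                    continue
                if any(abs(sides[perm[v]] - entry["sides"][v]) > bw * 1.5 for v in range(3)):
                    continue
                src = np.array([lig_pos[lidx[perm[v]]] for v in range(3)])
                dst = np.array([model_feats[midx[v]].position for v in range(3)])
                r, t = _kabsch(src, dst)
                lig_t = lig_pos @ r.T + t
                matched = _greedy_match(model_feats, lig_t, lig_types, tol)
                if len(matched) >= 3:
                    # refine on all matched pairs, then re-match once
                    src_all = np.array([lig_pos[lix] for _, lix in matched])
                    dst_all = np.array([model_feats[mix].position for mix, _ in matched])
                    r, t = _kabsch(src_all, dst_all)
                    lig_t = lig_pos @ r.T + t
                    matched = _greedy_match(model_feats, lig_t, lig_types, tol)
                if len(matched) < 3:
                    continue
                resid = [
                    np.linalg.norm(lig_t[lix] - model_feats[mix].position)
                    for mix, lix in matched
                ]
                rmsd = float(np.sqrt(np.mean(np.square(resid))))
                score = len(matched) / n_model
                if score > best.fit_score or (score == best.fit_score and rmsd < best.rmsd):
                    best = ScreenResult(
                        ligand_id=lig.ligand_id,
                        fit_score=score,
                        n_matched=len(matched),
                        rmsd=rmsd,
                        rotation=r,
                        translation=t,
                    )
                if best.fit_score >= 1.0 and best.rmsd < 1e-9:
                    return best
    if best.n_matched == 0:
        best.rmsd = 0.0
    return best


def screen_ligands(model: Pharmacophore, ligands: list, tol: float = 1.5,
                   bin_width: float = 0.5) -> list:
    index = triangle_index(model, bin_width=bin_width)
    return [match_ligand(index, lig, tol=tol) for lig in ligands]


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


def compute_ef(scores: list, fraction: float) -> float:
    """Enrichment factor at the given library fraction.

    ``scores`` is a list of (ligand_id, score, is_active). The library is
    ranked by score descending with ties broken by ligand id; the sampled
    set size is ceil(fraction x N).
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    n_total = len(scores)
    if n_total == 0:
        raise ValueError("empty score list")
    hits_total = sum(1 for _, _, act in scores if act)
    if hits_total == 0:
        raise ValueError("EF undefined without actives")
    ranked = sorted(scores, key=lambda t: (-t[1], str(t[0])))
    n_sampled = math.ceil(fraction * n_total)
    hits_sampled = sum(1 for _, _, act in ranked[:n_sampled] if act)
    return (hits_sampled / n_sampled) * (n_total / hits_total)


def compute_auc(scores: list) -> float:
    """Exact ROC AUC as the Mann-Whitney statistic (ties counted half).

    ``scores`` is a list of (score, is_active).
    """
    y = np.array([bool(act) for _, act in scores])
    s = np.array([float(v) for v, _ in scores])
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs at least one active and one decoy")
    ranks = rankdata(s)  # average ranks handle ties as half-wins
    return float((ranks[y].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def evaluate_screen(results: list, labels: dict, fractions=(0.01, 0.02, 0.05)) -> EnrichmentReport:
    """Build the AUC/EF report from screen results and an id->is_active map."""
    triplets = [(r.ligand_id, r.fit_score, bool(labels[r.ligand_id])) for r in results]
    auc = compute_auc([(s, a) for _, s, a in triplets])
    ef, per_fraction = {}, {}
    n_total = len(triplets)
    hits_total = sum(1 for _, _, a in triplets if a)
    ranked = sorted(triplets, key=lambda t: (-t[1], str(t[0])))
    for frac in fractions:
        ef[frac] = compute_ef(triplets, frac)
        n_sampled = math.ceil(frac * n_total)
        per_fraction[frac] = {
            "n_sampled": n_sampled,
            "hits_sampled": sum(1 for _, _, a in ranked[:n_sampled] if a),
        }
    return EnrichmentReport(auc=auc, ef=ef, n_total=n_total, hits_total=hits_total,
                            per_fraction=per_fraction)
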