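"""Pharmacophore assembly and serialization.

The polar pt1 representatives (HBA/HBD/POS/NEG) are validated against the
hybridization-projected pt2 sites: a pt1 point survives only if a pt2 site
of the same type lies within the 3 A merge radius (inclusive). Survivors —
the set pt3 — keep the grid-derived pt1 position and score (the energetic
evidence) and inherit the nearest pt2 site's direction (the geometric
evidence). The final model pt4 is pt3 together with the hydrophobic pt1
points and the aromatic features, giving six feature types in total.

Models serialize to a versioned JSON schema (lossless round trip) and to a
LigandScout-style PML export.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from xml.etree import ElementTree as ET

import numpy as np

from .aromatics import extract_aromatics
from .filtering import (
    FeaturePoint,
    FeatureType,
    FilterConfig,
    Provenance,
    filter_probe_map,
)
from .pocket import PocketGrid
from .probes import build_probe_map
from .projection import ConeParams, cone_geometry, extract_pt2
from .structure import ProteinStructure, assign_roles

logger = logging.getLogger(__name__)

POLAR_TYPES = (FeatureType.HBA, FeatureType.HBD, FeatureType.POS, FeatureType.NEG)
_TYPE_ORDER = [t.value for t in FeatureType]

JSON_FORMAT = "pocketpharm-pharmacophore"
JSON_VERSION = 1

#: LigandScout-style feature element names for the PML export.
_PML_NAMES = {
    FeatureType.HBA: "HBA",
    FeatureType.HBD: "HBD",
    FeatureType.POS: "PI",
    FeatureType.NEG: "NI",
    FeatureType.HYDROPHOBIC: "H",
    FeatureType.AROMATIC: "AR",
}


@dataclass
class Pharmacophore:
    features: list
    source: dict = field(default_factory=dict)
    config_snapshot: dict = field(default_factory=dict)

    def by_type(self, ftype: FeatureType) -> list:
        return [f for f in self.features if f.ftype is ftype]

    def type_counts(self) -> dict:
        out: dict = {}
        for f in self.features:
            out[f.ftype.value] = out.get(f.ftype.value, 0) + 1
        return out

    def __len__(self):
        return len(self.features)


def merge_pt1_pt2(pt1: list, pt2: list, merge_radius: float = 3.0) -> list:
    """Intersect polar pt1 with pt2 under the merge radius (inclusive).

    Only polar types participate; non-polar pt1 entries are ignored here.
    A surviving point keeps its pt1 position and score and gains the
    nearest same-type pt2 site's direction, with provenance MERGED.
    """
    out = []
    for fp in pt1:
        if fp.ftype not in POLAR_TYPES:
            continue
        same = [q for q in pt2 if q.ftype is fp.ftype]
        if not same:
            continue
        dists = [float(np.linalg.norm(q.position - fp.position)) for q in same]
        k = int(np.argmin(dists))
        if dists[k] <= merge_radius + 1e-9:
            merged = fp.with_direction(same[k].direction, Provenance.MERGED)
            merged.source = same[k].source
            out.append(merged)
    return out


def _sort_key(fp: FeaturePoint):
    return (_TYPE_ORDER.index(fp.ftype.value), round(fp.position[0], 6),
            round(fp.position[1], 6), round(fp.position[2], 6))


def build_model(
    pt1: list,
    pt2: list,
    aromatics: list,
    cfg: FilterConfig | None = None,
    cone: ConeParams | None = None,
    source: dict | None = None,
) -> Pharmacophore:
    """Assemble pt4 = merge(polar pt1, pt2) + hydrophobic pt1 + aromatics."""
    cfg = cfg or FilterConfig()
    cone = cone or cone_geometry()
    pt3 = merge_pt1_pt2(pt1, pt2, cfg.merge_radius)
    hydrophobic = [f for f in pt1 if f.ftype is FeatureType.HYDROPHOBIC]
    features = sorted(pt3 + hydrophobic + list(aromatics), key=_sort_key)
    if not features:
        logger.warning("pharmacophore model is empty")
    return Pharmacophore(
        features=features,
        source=source or {},
        config_snapshot={
            "filter": cfg.to_dict(),
            "cone": {"c": cone.c, "d": cone.d, "e": cone.e},
        },
    )


def generate_pharmacophore(
    structure: ProteinStructure,
    grid: PocketGrid,
    cfg: FilterConfig | None = None,
    cone: ConeParams | None = None,
    source: dict | None = None,
) -> Pharmacophore:
    """Run the full receptor-only pipeline on a structure + pocket grid."""
    cfg = cfg or FilterConfig()
    cone = cone or cone_geometry()
    if not any(a.roles for a in structure.atoms):
        assign_roles(structure)
    pmap = build_probe_map(grid, structure)
    pt1 = filter_probe_map(pmap, cfg)
    pt2 = extract_pt2(structure, grid, cone)
    hydrophobic = [f for f in pt1 if f.ftype is FeatureType.HYDROPHOBIC]
    aromatics = extract_aromatics(hydrophobic, structure, grid, cfg)
    return build_model(pt1, pt2, aromatics, cfg, cone, source=source)


def distill_model(model: Pharmacophore, per_type: int = 1) -> Pharmacophore:
    """Compact query model: the ``per_type`` highest-scoring features of each
    type. Useful for screening, where a handful of anchor features per type
    is a far more selective query than every representative point."""
    feats = []
    for ftype in FeatureType:
        cand = sorted(model.by_type(ftype), key=lambda f: (-f.score, _sort_key(f)))
        feats.extend(cand[:per_type])
    return Pharmacophore(
        features=sorted(feats, key=_sort_key),
        source=model.source,
        config_snapshot=model.config_snapshot,
    )


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def _feature_to_dict(fp: FeaturePoint) -> dict:
    return {
        "type": fp.ftype.value,
        "position": [float(x) for x in fp.position],
        "score": float(fp.score),
        "direction": None if fp.direction is None else [float(x) for x in fp.direction],
        "tolerance": float(fp.tolerance),
        "provenance": fp.provenance.value,
        "source": fp.source,
    }


def _feature_from_dict(d: dict, path: str) -> FeaturePoint:
    try:
        return FeaturePoint(
            ftype=FeatureType(d["type"]),
            position=np.array(d["position"], dtype=float),
            score=float(d["score"]),
            direction=None if d.get("direction") is None else np.array(d["direction"], dtype=float),
            tolerance=float(d.get("tolerance", 1.5)),
            provenance=Provenance(d.get("provenance", "PT1")),
            source=d.get("source"),
        )
    except (KeyError, ValueError, TypeError) as exc:
        raise ValueError(f"schema error at {path}: {exc}") from exc


def write_model(model: Pharmacophore, fmt: str = "JSON") -> str:
    fmt = fmt.upper()
    if fmt == "JSON":
        doc = {
            "format": JSON_FORMAT,
            "version": JSON_VERSION,
            "source": model.source,
            "config": model.config_snapshot,
            "features": [_feature_to_dict(f) for f in model.features],
        }
        return json.dumps(doc, indent=2, sort_keys=True) + "\n"
    if fmt == "PML":
        root = ET.Element("pharmacophore", name="pocketpharm", pharmacophoreType="LIGAND_SCOUT")
        for i, fp in enumerate(model.features):
            name = _PML_NAMES[fp.ftype]
            if fp.direction is not None and fp.ftype in (FeatureType.HBA, FeatureType.HBD):
                el = ET.SubElement(root, "vector", name=name, featureId=str(i),
                                   pointsToLigand="true", optional="false", disabled="false")
                origin = fp.position
                target = fp.position + 2.0 * fp.direction
                ET.SubElement(el, "origin", x3=f"{origin[0]:.4f}", y3=f"{origin[1]:.4f}",
                              z3=f"{origin[2]:.4f}", tolerance=f"{fp.tolerance:.3f}")
                ET.SubElement(el, "target", x3=f"{target[0]:.4f}", y3=f"{target[1]:.4f}",
                              z3=f"{target[2]:.4f}", tolerance=f"{fp.tolerance:.3f}")
            elif fp.ftype is FeatureType.AROMATIC and fp.direction is not None:
                el = ET.SubElement(root, "plane", name=name, featureId=str(i),
                                   optional="false", disabled="false")
                ET.SubElement(el, "position", x3=f"{fp.position[0]:.4f}",
                              y3=f"{fp.position[1]:.4f}", z3=f"{fp.position[2]:.4f}",
                              tolerance=f"{fp.tolerance:.3f}")
                ET.SubElement(el, "normal", x3=f"{fp.direction[0]:.4f}",
                              y3=f"{fp.direction[1]:.4f}", z3=f"{fp.direction[2]:.4f}",
                              tolerance="0.45")
            else:
                el = ET.SubElement(root, "point", name=name, featureId=str(i),
                                   optional="false", disabled="false")
                ET.SubElement(el, "position", x3=f"{fp.position[0]:.4f}",
                              y3=f"{fp.position[1]:.4f}", z3=f"{fp.position[2]:.4f}",
                              tolerance=f"{fp.tolerance:.3f}")
        ET.indent(root)
        return ET.tostring(root, encoding="unicode") + "\n"
    raise ValueError(f"unknown model format: {fmt!r}")


def read_model(stream: str) -> Pharmacophore:
    """Read a model from its JSON serialization (the lossless format)."""
    try:
        doc = json.loads(stream)
    except json.JSONDecodeError as exc:
        raise ValueError(f"schema error at $: not valid JSON ({exc})") from exc
    if not isinstance(doc, dict) or doc.get("format") != JSON_FORMAT:
        raise ValueError("schema error at $.format: not a pocketpharm pharmacophore")
    features = [
        _feature_from_dict(d, f"$.features[{i}]") for i, d in enumerate(doc.get("features", []))
    ]
    return Pharmacophore(
        features=features,
        source=doc.get("source", {}),
        config_snapshot=doc.get("config", {}),
    )
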