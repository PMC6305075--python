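"""Filter-stage tests, including brute-force oracle equivalence.

The oracle re-implements the three stages with plain O(n^2) loops: zero
scores strictly below the threshold, keep points whose same-type nonzero
neighbor count (distance <= radius, excluding self) strictly exceeds the
count threshold, then greedy highest-score-first suppression at 2.5 A with
coordinate tie-breaks. Inclusive boundaries carry the implementation's
documented 1e-9 metric slack.
"""

import numpy as np
import pytest

from pocketpharm.filtering import (
    FeaturePoint,
    FilterConfig,
    filter_probe_map,
    neighbor_filter,
    select_representatives,
    threshold_map,
)
from pocketpharm.pocket import PocketGrid
from pocketpharm.probes import PROBE_ORDER, ProbeMap, ProbeType


def make_map(points, scores, spacing=0.5):
    return ProbeMap(
        grid=PocketGrid(points=np.asarray(points, float), spacing=spacing),
        scores=np.asarray(scores, float),
    )


def single_type_map(points, values, probe=ProbeType.HBD, spacing=0.5):
    scores = np.zeros((len(points), 5))
    scores[:, PROBE_ORDER.index(probe)] = values
    return make_map(points, scores, spacing)


# ---------------------------------------------------------------------------
# brute-force oracle
# ---------------------------------------------------------------------------


def oracle_pipeline(points, scores, cfg):
    points = np.asarray(points, float)
    scores = np.array(scores, float, copy=True)
    for col, probe in enumerate(PROBE_ORDER):
        thr = cfg.score_threshold[probe]
        for i in range(len(points)):
            if scores[i, col] < thr - 1e-12:
                scores[i, col] = 0.0
    out = np.array(scores, copy=True)
    for col, probe in enumerate(PROBE_ORDER):
        thr = cfg.neighbor_threshold[probe]
        for i in range(len(points)):
            if scores[i, col] <= 0:
                continue
            count = sum(
                1
                for j in range(len(points))
                if j != i
                and scores[j, col] > 0
                and np.linalg.norm(points[i] - points[j]) <= cfg.neighbor_radius + 1e-9
            )
            if not count > thr:
                out[i, col] = 0.0
    scores = out
    reps = []
    for col, probe in enumerate(PROBE_ORDER):
        nz = [i for i in range(len(points)) if scores[i, col] > 0]
        spread = {
            i: sum(float(np.linalg.norm(points[i] - points[j])) for j in nz) for i in nz
        }
        alive = list(nz)
        while alive:
            best = min(
                alive,
                key=lambda i: (
                    -round(scores[i, col], 9),
                    round(spread[i], 5),
                    points[i, 0],
                    points[i, 1],
                    points[i, 2],
                    i,
                ),
            )
            reps.append(
                (
                    probe.value,
                    tuple(round(float(c), 9) for c in points[best]),
                    round(float(scores[best, col]), 9),
                )
            )
            alive = [
                i
                for i in alive
                if np.linalg.norm(points[i] - points[best]) > cfg.representative_radius + 1e-9
            ]
    return reps


def as_tuples(features):
    return [
        (
            f.ftype.value,
            tuple(round(float(c), 9) for c in f.position),
            round(float(f.score), 9),
        )
        for f in features
    ]


# ---------------------------------------------------------------------------
# stage examples
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "probe, value, survives",
    [
        (ProbeType.HBD, 0.15, True),  # boundary value survives (strict-less rule)
        (ProbeType.HBD, 0.149, False),
        (ProbeType.POS, 0.4, False),
        (ProbeType.NEG, 0.6, True),
        (ProbeType.HYDROPHOBIC, 0.2, True),
        (ProbeType.HYDROPHOBIC, 0.1999, False),
    ],
)
def test_threshold_boundaries(probe, value, survives):
    pmap = single_type_map([[0, 0, 0]], [value], probe)
    out = threshold_map(pmap, FilterConfig())
    kept = out.column(probe)[0]
    assert (kept == value) if survives else (kept == 0.0)


def test_isolated_point_fails_neighbor_count():
    pmap = single_type_map([[0, 0, 0]], [0.9], ProbeType.HBD)
    out = neighbor_filter(pmap, FilterConfig())
    assert out.column(ProbeType.HBD)[0] == 0.0


@pytest.mark.parametrize("n_neighbors, kept", [(5, False), (6, True)])
def test_charge_neighbor_count_is_strictly_greater(n_neighbors, kept):
    # center point plus n lattice neighbors inside the 2 A count radius
    offsets = [
        [0.5, 0, 0], [-0.5, 0, 0], [0, 0.5, 0], [0, -0.5, 0], [0, 0, 0.5], [0, 0, -0.5],
    ]
    pts = [[0.0, 0.0, 0.0]] + offsets[:n_neighbors]
    assert all(np.linalg.norm(p) <= 2.0 for p in pts[1:])
    pmap = single_type_map(pts, [0.9] * len(pts), ProbeType.POS)
    out = neighbor_filter(pmap, FilterConfig())
    assert bool(out.column(ProbeType.POS)[0] > 0) is kept


def test_nms_keeps_single_point():
    pmap = single_type_map([[1.0, 2.0, 3.0]], [0.7])
    cfg = FilterConfig()
    feats = select_representatives(pmap, cfg)
    assert len(feats) == 1
    np.testing.assert_allclose(feats[0].position, [1, 2, 3])
    assert feats[0].score == 0.7


def test_nms_suppresses_within_radius_and_keeps_beyond():
    close = single_type_map([[0, 0, 0], [2.0, 0, 0]], [0.9, 0.8])
    far = single_type_map([[0, 0, 0], [3.0, 0, 0]], [0.9, 0.8])
    cfg = FilterConfig()
    assert len(select_representatives(close, cfg)) == 1
    assert len(select_representatives(far, cfg)) == 2


# ---------------------------------------------------------------------------
# oracle equivalence and invariants
# ---------------------------------------------------------------------------


def random_map(rng, n_max=200):
    """Random probe map stressing every boundary: exact threshold scores,
    exactly-at-radius spacings, dense blobs around the count thresholds."""
    n = int(rng.integers(20, n_max + 1))
    pts = np.round(rng.uniform(0, 4.0, size=(n, 3)) * 2) / 2  # 0.5 A lattice
    # dedupe lattice collisions to keep the oracle well-defined under ties
    pts = np.unique(pts, axis=0)
    n = len(pts)
    scores = rng.uniform(0, 1, size=(n, 5))
    scores[rng.uniform(size=(n, 5)) < 0.3] = 0.0
    # plant exact boundary scores
    for value in (0.15, 0.2, 0.5):
        idx = rng.integers(0, n, size=3)
        col = rng.integers(0, 5, size=3)
        scores[idx, col] = value
    return pts, scores


def test_pipeline_matches_bruteforce_oracle(rng):
    cfg = FilterConfig()
    for _ in range(30):
        pts, scores = random_map(rng)
        pmap = make_map(pts, scores)
        got = as_tuples(filter_probe_map(pmap, cfg))
        expected = oracle_pipeline(pts, scores, cfg)
        assert sorted(map(repr, got)) == sorted(map(repr, expected))


def test_pipeline_invariant_to_point_order(rng):
    cfg = FilterConfig()
    pts, scores = random_map(rng, n_max=80)
    base = as_tuples(filter_probe_map(make_map(pts, scores), cfg))
    perm = rng.permutation(len(pts))
    shuffled = as_tuples(filter_probe_map(make_map(pts[perm], scores[perm]), cfg))
    assert sorted(map(repr, base)) == sorted(map(repr, shuffled))


def test_representatives_dominate_their_region_and_are_spaced(rng):
    cfg = FilterConfig()
    pts, scores = random_map(rng, n_max=120)
    pmap = neighbor_filter(threshold_map(make_map(pts, scores), cfg), cfg)
    feats = select_representatives(pmap, cfg)
    for col, probe in enumerate(PROBE_ORDER):
        reps = [f for f in feats if f.ftype.value == probe.value]
        # each representative dominates the region it suppressed (emission order)
        remaining = {i for i in range(len(pts)) if pmap.scores[i, col] > 0}
        for f in reps:
            region = {
                i for i in remaining if np.linalg.norm(pts[i] - f.position) <= 2.5
            }
            for i in region:
                assert f.score >= pmap.scores[i, col] - 2e-9
            remaining -= region
        assert not remaining  # NMS runs to exhaustion
        for i, a in enumerate(reps):
            for b in reps[i + 1:]:
                assert np.linalg.norm(a.position - b.position) > cfg.representative_radius


def test_config_ini_roundtrip():
    cfg = FilterConfig()
    cfg.score_threshold[ProbeType.POS] = 0.42
    cfg.neighbor_radius = 1.75
    back = FilterConfig.from_ini(cfg.to_ini())
    assert back.score_threshold[ProbeType.POS] == 0.42
    assert back.neighbor_radius == 1.75
    assert back.neighbor_threshold == cfg.neighbor_threshold


def test_feature_point_validation():
    from pocketpharm.filtering import FeatureType

    with pytest.raises(ValueError):
        FeaturePoint(ftype=FeatureType.HBD, position=[0, 0], score=1.0)
    with pytest.raises(ValueError):
        FeaturePoint(ftype=FeatureType.HBD, position=[0, 0, 0], score=1.0, direction=[0.5, 0, 0])
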