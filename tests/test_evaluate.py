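"""FAR/FRR/EER sweep, min-max normalization, weighted-sum fusion, pipeline."""

import json
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from veinverify.evaluate import (EvalResult, PipelineConfig, far_frr, minmax_normalize,
                                 fuse_and_search, run_pipeline)
from veinverify.matching import DistanceMatrix, distance_matrix
from veinverify.synthgen import LabelledDataset


def oracle_eer(genuine, impostor):
    """Scalar brute-force threshold sweep with the same crossing definition."""
    taus = sorted(set(genuine) | set(impostor))
    pts = [(taus[0], 0.0, 1.0)]                   # virtual point below all scores
    for tau in taus:
        far = sum(1 for s in impostor if s <= tau) / len(impostor)
        frr = sum(1 for s in genuine if s > tau) / len(genuine)
        pts.append((tau, far, frr))
    for (t0, f0, r0), (t1, f1, r1) in zip(pts, pts[1:]):
        if f1 - r1 >= 0:
            if f1 == r1:
                return 100.0 * f1
            denom = (f1 - f0) + (r0 - r1)
            alpha = (r0 - f0) / denom if denom > 0 else 0.5
            return 100.0 * (f0 + alpha * (f1 - f0))
    raise AssertionError("FAR(max) = 1, FRR(max) = 0: a crossing always exists")


def test_perfect_separation_zero_eer():
    res = far_frr([0.1, 0.2], [0.8, 0.9])
    assert res.eer == 0.0
    assert np.all(np.diff(res.far) >= 0)
    assert np.all(np.diff(res.frr) <= 0)


def test_empty_scores_rejected():
    with pytest.raises(ValueError):
        far_frr([], [0.5])


def test_inverted_singleton_matches_oracle():
    g, i = [0.3], [0.1]
    assert far_frr(g, i).eer == pytest.approx(oracle_eer(g, i), abs=1e-9)


@settings(derandomize=True, max_examples=60, deadline=None)
@given(
    st.lists(st.floats(0, 1, allow_nan=False, width=32), min_size=1, max_size=25),
    st.lists(st.floats(0, 1, allow_nan=False, width=32), min_size=1, max_size=25),
)
def test_eer_matches_brute_force_sweep(genuine, impostor):
    assert far_frr(genuine, impostor).eer == pytest.approx(
        oracle_eer(genuine, impostor), abs=1e-9)


def test_exchangeable_scores_give_50_percent():
    rng = np.random.default_rng(99)
    g = rng.normal(size=10_000)
    i = rng.normal(size=10_000)
    assert far_frr(g, i).eer == pytest.approx(50.0, abs=2.0)


def test_eer_invariant_under_monotone_transform(rng):
    g = rng.normal(0.0, 1.0, 300)
    i = rng.normal(1.0, 1.0, 300)
    base = far_frr(g, i).eer
    assert far_frr(np.exp(g), np.exp(i)).eer == pytest.approx(base, abs=1e-9)
    assert far_frr(3 * g + 7, 3 * i + 7).eer == pytest.approx(base, abs=1e-9)


def _dm_from_values(values, ts, es):
    return DistanceMatrix(values=np.asarray(values, dtype=float), metric="euclidean",
                          test_subjects=np.asarray(ts), enroll_subjects=np.asarray(es))


def test_minmax_normalize(rng):
    d = _dm_from_values([[1.0, 3.0], [5.0, 3.0]], [0, 1], [0, 1])
    n = minmax_normalize(d)
    assert n.values.min() == 0.0 and n.values.max() == 1.0
    assert np.allclose(np.unique(n.values), [0.0, 0.5, 1.0])
    # monotone map: single-channel EER unchanged
    g, i = d.genuine_scores(), d.impostor_scores()
    assert far_frr(n.genuine_scores(), n.impostor_scores()).eer == \
        pytest.approx(far_frr(g, i).eer, abs=1e-9)
    with pytest.warns(UserWarning, match="constant"):
        z = minmax_normalize(_dm_from_values([[2.0, 2.0]], [0], [0, 1]))
    assert np.all(z.values == 0.0)


def test_fusion_identical_channels_is_identity(rng):
    v = rng.random((6, 6))
    ts = es = np.arange(6) // 2
    d = _dm_from_values(v, ts, es)
    single = far_frr(d.genuine_scores(), d.impostor_scores()).eer
    fr = fuse_and_search(d, _dm_from_values(v.copy(), ts, es))
    assert fr.result.eer == pytest.approx(single, abs=1e-9)
    assert np.allclose(fr.eers, single, atol=1e-9)


def test_fused_eer_never_exceeds_endpoints(rng):
    ts = rng.integers(0, 4, size=8)
    es = rng.integers(0, 4, size=10)
    for _ in range(5):
        d1 = _dm_from_values(rng.random((8, 10)), ts, es)
        d2 = _dm_from_values(rng.random((8, 10)), ts, es)
        fr = fuse_and_search(d1, d2, step=0.05)
        assert fr.result.eer <= fr.eers[0] + 1e-9
        assert fr.result.eer <= fr.eers[-1] + 1e-9


def test_complementary_channels_interior_weight():
    """Channel 1 separates subject 0, channel 2 subject 1; each alone has
    50% EER but an interior weight separates everything."""
    ts = es = np.array([0, 1])
    d1 = _dm_from_values([[0.1, 0.55], [0.55, 0.9]], ts, es)
    d2 = _dm_from_values([[0.9, 0.55], [0.55, 0.1]], ts, es)
    fr = fuse_and_search(d1, d2)
    assert 0.0 < fr.weight < 1.0
    assert fr.result.eer < min(fr.eers[0], fr.eers[-1])
    assert fr.result.eer == 0.0


def test_fusion_shape_mismatch_rejected(rng):
    d1 = _dm_from_values(rng.random((2, 3)), [0, 1], [0, 1, 1])
    d2 = _dm_from_values(rng.random((3, 3)), [0, 1, 1], [0, 1, 1])
    with pytest.raises(ValueError):
        fuse_and_search(d1, d2)


def test_pipeline_zero_jitter_gives_zero_eer(clean_dataset):
    cfg = PipelineConfig(experiments=("full",),
                         metrics=("euclidean", "cosine"))
    report = run_pipeline(clean_dataset, cfg)
    for row in report["experiments"]["full"]["per_metric"].values():
        assert row["wlpp_eer"] == pytest.approx(0.0, abs=1e-8)
        assert row["lbpv_lpp_eer"] == pytest.approx(0.0, abs=1e-8)
        assert row["fused_eer"] == pytest.approx(0.0, abs=1e-8)
    assert report["identification_accuracy_wlpp"] == 1.0


def test_pipeline_deterministic(tiny_dataset):
    cfg = PipelineConfig(experiments=("full",), metrics=("euclidean",))
    r1 = run_pipeline(tiny_dataset, cfg)
    r2 = run_pipeline(tiny_dataset, cfg)
    assert json.dumps(r1, sort_keys=True) == json.dumps(r2, sort_keys=True)


def test_pipeline_requires_split(tiny_dataset):
    bare = LabelledDataset(images=tiny_dataset.images, split=[])
    with pytest.raises(ValueError):
        run_pipeline(bare)
    with pytest.raises(ValueError):
        PipelineConfig(experiments=("nope",))
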