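"""SMDR pipeline: decomposition exactness, differential solve, post-processing."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import eit_smdr as es
from eit_smdr.cluster import ARTIFACT, BACKGROUND, MIXTURE, OBJECT
from eit_smdr.recon import tikhonov_dual
from eit_smdr.smdr import (
    decompose_sensitivity,
    differential_rereconstruct,
    filter_normalize,
    postprocess,
)


@given(st.lists(st.integers(min_value=1, max_value=4), min_size=5, max_size=40),
       st.integers(0, 2**31 - 1))
def test_decomposition_partitions_columns_exactly(labels, seed):
    labels = np.asarray(labels)
    S0 = np.random.default_rng(seed).normal(size=(7, len(labels)))
    dec = decompose_sensitivity(S0, labels)
    total = dec[1] + dec[2] + dec[3] + dec[4]
    assert np.array_equal(total, S0)  # entrywise exact, no tolerance
    for c in (1, 2, 3, 4):
        nonzero_cols = np.flatnonzero(np.any(dec[c] != 0, axis=0))
        assert set(nonzero_cols) <= set(np.flatnonzero(labels == c))


def test_single_cluster_edge_case():
    S0 = np.arange(12.0).reshape(3, 4) + 1.0
    dec = decompose_sensitivity(S0, np.full(4, BACKGROUND))
    assert np.array_equal(dec[BACKGROUND], S0)
    for c in (OBJECT, MIXTURE, ARTIFACT):
        assert np.all(dec[c] == 0)


def test_label_length_mismatch_rejected():
    with pytest.raises(ValueError):
        decompose_sensitivity(np.eye(4), np.array([1, 2, 3]))


def test_differential_equals_difference_of_independent_solves():
    rng = np.random.default_rng(8)
    S0 = rng.normal(size=(15, 30))
    labels = rng.integers(1, 5, size=30)
    d = rng.normal(size=15)
    lam = 0.2
    dec = decompose_sensitivity(S0, labels)
    out = differential_rereconstruct(dec, d, lam)
    S123 = S0.copy()
    S123[:, labels == BACKGROUND] = 0.0
    S3 = np.where(labels == ARTIFACT, S0, 0.0)
    ref = tikhonov_dual(S123, d, lam) - tikhonov_dual(S3, d, lam)
    assert np.abs(out - ref).max() < 1e-12


def test_empty_artifact_cluster_reduces_to_working_area_solve():
    rng = np.random.default_rng(9)
    S0 = rng.normal(size=(10, 20))
    labels = np.array([OBJECT] * 5 + [MIXTURE] * 5 + [BACKGROUND] * 10)
    d = rng.normal(size=10)
    dec = decompose_sensitivity(S0, labels)
    out = differential_rereconstruct(dec, d, 0.5)
    S12 = np.where((labels == OBJECT) | (labels == MIXTURE), S0, 0.0)
    assert np.allclose(out, tikhonov_dual(S12, d, 0.5), atol=1e-12)


def test_empty_working_area_rejected():
    S0 = np.eye(4)
    dec = decompose_sensitivity(S0, np.full(4, BACKGROUND))
    with pytest.raises(ValueError):
        differential_rereconstruct(dec, np.ones(4), 0.1)


# -- filtering and post-processing ---------------------------------------


def test_filter_normalize_range_and_idempotence():
    v = np.array([-2.0, 0.0, 1.0, 4.0, 3.0])
    out = filter_normalize(v)
    assert np.array_equal(out, [0.0, 0.0, 0.25, 1.0, 0.75])
    assert out.max() == 1.0
    assert np.array_equal(filter_normalize(out), out)  # h(h(x)) = h(x)


def test_filter_normalize_flags_absent_object():
    out = filter_normalize(np.array([-1.0, -0.5, 0.0]))
    assert np.all(out == 0.0)


def test_postprocess_zeroes_artifact_and_background():
    rng = np.random.default_rng(3)
    v = filter_normalize(rng.normal(0.2, 0.5, size=200))
    out, clusters = postprocess(v, seed=0)
    low = (clusters.labels == ARTIFACT) | (clusters.labels == BACKGROUND)
    assert np.all(out[low] == 0.0)
    keep = (clusters.labels == OBJECT) | (clusters.labels == MIXTURE)
    assert np.array_equal(out[keep], v[keep])  # pass through unchanged
    assert np.count_nonzero(out) <= np.count_nonzero(v)  # support shrinks


# -- full pipeline -------------------------------------------------------


def test_zero_frame_reports_absent_object(bench_model):
    est = es.SMDRReconstructor(lam=1e-6).fit(bench_model.sensitivity)
    res = est.reconstruct(np.zeros(len(bench_model.protocol)))
    assert res.object_absent
    assert np.all(res.image == 0.0)


def test_pipeline_output_contract(bench_model):
    """Final image in [0,1], masked pixels 0, support inside labels 1-2."""
    model = bench_model
    ph = es.make_case(2)
    dU, _ = model.simulate(ph, snr_db=60, seed=4)
    est = es.SMDRReconstructor(lam="auto", random_state=4).fit(model.sensitivity)
    res = est.reconstruct(dU.values)
    assert res.image.min() >= 0.0 and res.image.max() <= 1.0
    keep = (res.clusters_post.labels == OBJECT) | (res.clusters_post.labels == MIXTURE)
    assert np.all(res.image[~keep] == 0.0)
    img = model.grid.embed(res.image)
    assert np.all(img[~model.grid.mask] == 0.0)


def test_pipeline_sharpens_support_and_correlation(bench_model):
    """Noiseless two-inclusion phantom: SMDR support is sparser than the
    positive part of the initial image, and the location-compensated CC
    (the evaluation protocol for every reconstruction) does not degrade."""
    model = bench_model
    ph = es.Phantom(inclusions=(es.Inclusion((0.4, 0.2), 0.2, 2.0),
                                es.Inclusion((-0.4, -0.2), 0.2, 2.0)))
    dU, truth = model.simulate(ph)
    est = es.SMDRReconstructor(lam="auto", random_state=0).fit(model.sensitivity)
    res = est.reconstruct(dU.values)
    assert np.count_nonzero(res.image) < np.count_nonzero(res.initial > 0)
    t = model.grid.extract(truth)
    comp = lambda v: es.location_compensate(v, model.grid)
    assert es.cc(comp(res.image), t) >= es.cc(comp(res.initial), t)


def test_transform_stacks_frames(bench_model):
    model = bench_model
    ph = es.make_case(1)
    dU, _ = model.simulate(ph, snr_db=60, seed=0)
    est = es.SMDRReconstructor(random_state=0).fit(model.sensitivity)
    single = est.transform(dU.values)
    stacked = est.transform(np.vstack([dU.values, dU.values]))
    assert stacked.shape == (2, model.grid.M)
    assert np.array_equal(stacked[0], single)


def test_functional_wrapper_matches_estimator(bench_model):
    model = bench_model
    ph = es.make_case(4)
    dU, _ = model.simulate(ph, snr_db=50, seed=2)
    a = es.smdr(model.sensitivity, dU.values, seed=2)
    b = es.SMDRReconstructor(lam="auto", random_state=2).fit(model.sensitivity).reconstruct(dU.values)
    assert np.array_equal(a, b.image)
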