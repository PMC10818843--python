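"""Phantom library, field mapping, truth rasterization, and the noise model."""

import numpy as np
import pytest

import eit_smdr as es
from eit_smdr.phantom import CASE_IDS, make_case, noise_std, truth_image


@pytest.fixture(scope="module")
def grid():
    return es.PixelGrid(side=64, radius=1.0)


@pytest.mark.parametrize("case", CASE_IDS)
def test_library_cases_use_two_phase_conductivities(case):
    ph = make_case(case)
    assert ph.background_conductivity == 1.0
    assert all(inc.conductivity == 2.0 for inc in ph.inclusions)
    assert len(ph.inclusions) >= 1


def test_case_library_layouts():
    counts = {c: len(make_case(c).inclusions) for c in CASE_IDS}
    assert counts[1] == 3 and counts[4] == 4 and counts[5] == 10
    assert any(i.shape == "square" for i in make_case(6).inclusions)


def test_random_phantom_deterministic_and_non_overlapping():
    a = make_case("random", seed=42)
    b = make_case("random", seed=42)
    assert a == b
    for i, p in enumerate(a.inclusions):
        for q in a.inclusions[i + 1:]:
            d = np.hypot(p.center[0] - q.center[0], p.center[1] - q.center[1])
            assert d >= p.radius + q.radius


def test_unsatisfiable_spec_rejected():
    with pytest.raises(ValueError):
        make_case("random", seed=0, n_inclusions=(3, 3), radius_range=(0.45, 0.5))


def test_inclusion_outside_domain_rejected():
    with pytest.raises(ValueError):
        es.Phantom(inclusions=(es.Inclusion((0.9, 0.0), 0.3, 2.0),))


def test_phantom_to_field_values(coarse_mesh):
    empty = es.Phantom()
    assert np.all(es.phantom_to_field(empty, coarse_mesh) == 1.0)
    full = es.Phantom(inclusions=(es.Inclusion((0.0, 0.0), 1.0, 2.0),))
    assert np.all(es.phantom_to_field(full, coarse_mesh) == 2.0)
    ph = make_case(1)
    field = es.phantom_to_field(ph, coarse_mesh)
    assert set(np.unique(field)) == {1.0, 2.0}


def test_truth_image_area_counting(grid):
    """A radius-0.2 disk covers ~ pi 0.2^2 / pixel_area interior pixels."""
    ph = es.Phantom(inclusions=(es.Inclusion((0.0, 0.0), 0.2, 2.0),))
    img = truth_image(ph, grid)
    count = int(np.sum(img > 0))
    expected = np.pi * 0.2**2 / grid.pixel_area
    assert abs(count - expected) / expected < 0.05
    assert np.all(img[~grid.mask] == 0)


def test_empty_phantom_gives_zero_frame(coarse_mesh, protocol16, grid):
    dU, truth = es.simulate_frame(es.Phantom(), coarse_mesh, protocol16, grid)
    assert np.allclose(dU.values, 0.0, atol=1e-14)
    assert np.all(truth == 0)


def test_central_inclusion_weaker_than_peripheral(coarse_mesh, protocol16):
    """Central objects produce weaker boundary signals (low central sensitivity)."""
    central = es.Phantom(inclusions=(es.Inclusion((0.0, 0.0), 0.15, 2.0),))
    boundary = es.Phantom(inclusions=(es.Inclusion((0.7, 0.0), 0.15, 2.0),))
    dc, _ = es.simulate_frame(central, coarse_mesh, protocol16)
    db, _ = es.simulate_frame(boundary, coarse_mesh, protocol16)
    assert np.linalg.norm(dc.values) < np.linalg.norm(db.values)


# -- noise model ---------------------------------------------------------


def _long_frame(n=100_000, seed=1):
    protocol = es.Protocol(n_electrodes=16, patterns=np.zeros((n, 4), dtype=np.intp))
    rng = np.random.default_rng(seed)
    return es.VoltageFrame(values=rng.normal(1.0, 0.5, n), protocol=protocol)


def test_noiseless_spec_is_identity():
    fr = _long_frame(n=500)
    out = es.add_noise(fr, es.NoiseSpec(snr_db=None))
    assert np.array_equal(out.values, fr.values)


def test_noise_deterministic_given_seed():
    fr = _long_frame(n=500)
    a = es.add_noise(fr, es.NoiseSpec(50, seed=7))
    b = es.add_noise(fr, es.NoiseSpec(50, seed=7))
    c = es.add_noise(fr, es.NoiseSpec(50, seed=8))
    assert np.array_equal(a.values, b.values)
    assert not np.array_equal(a.values, c.values)


def test_empirical_snr_matches_nominal():
    """Over 1e5 channels the realised SNR is within 0.2 dB of 50 dB."""
    fr = _long_frame()
    noisy = es.add_noise(fr, es.NoiseSpec(50, seed=3))
    eps = noisy.values - fr.values
    rms = lambda x: np.sqrt(np.mean(np.square(x)))
    empirical = 20 * np.log10(rms(fr.values) / rms(eps))
    assert abs(empirical - 50.0) < 0.2
    assert abs(eps.mean()) < 5 * eps.std() / np.sqrt(len(eps))  # zero-mean


def test_zero_frame_with_finite_snr_rejected(protocol16):
    fr = es.VoltageFrame(values=np.zeros(len(protocol16)), protocol=protocol16)
    with pytest.raises(ValueError):
        es.add_noise(fr, es.NoiseSpec(50, seed=0))
    with pytest.raises(ValueError):
        noise_std(fr, 50)


def test_negative_snr_rejected():
    with pytest.raises(ValueError):
        es.NoiseSpec(snr_db=-10)


def test_negate_frame(protocol16):
    fr = es.VoltageFrame(values=np.arange(len(protocol16), dtype=float), protocol=protocol16)
    assert np.array_equal(es.negate_frame(fr).values, -fr.values)
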