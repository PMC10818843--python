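"""Tikhonov solver, GCV selection, and location compensation."""

import numpy as np
import pytest
from sklearn.base import clone

import eit_smdr as es
from eit_smdr.recon import TikhonovReconstructor, tikhonov_dual


def test_identity_system_closed_forms():
    """S = I: lambda=0 returns dU exactly; lambda=1 returns dU/2."""
    d = np.array([3.0, -1.0, 2.0, 0.5, -4.0])
    S = np.eye(5)
    x0 = TikhonovReconstructor(lam=0.0).fit(S).transform(d)
    assert np.abs(x0 - d).max() < 1e-12
    x1 = TikhonovReconstructor(lam=1.0).fit(S).transform(d)
    assert np.abs(x1 - d / 2.0).max() < 1e-12


def test_matches_augmented_least_squares_oracle():
    """(S^T S + lam I)^-1 S^T d == argmin ||[S; sqrt(lam) I] x - [d; 0]||."""
    rng = np.random.default_rng(5)
    S = rng.normal(size=(20, 30))
    d = rng.normal(size=20)
    for lam in (1e-3, 0.37, 2.0):
        x = TikhonovReconstructor(lam=lam).fit(S).transform(d)
        A = np.vstack([S, np.sqrt(lam) * np.eye(30)])
        b = np.concatenate([d, np.zeros(30)])
        ref = np.linalg.lstsq(A, b, rcond=None)[0]
        assert np.abs(x - ref).max() < 1e-8
        # dual form agrees too
        assert np.abs(tikhonov_dual(S, d, lam) - ref).max() < 1e-8


def test_zero_lambda_on_rank_deficient_system_rejected():
    rng = np.random.default_rng(0)
    S = rng.normal(size=(20, 30))  # underdetermined -> singular normal equations
    with pytest.raises(np.linalg.LinAlgError):
        TikhonovReconstructor(lam=0.0).fit(S).transform(rng.normal(size=20))


def test_solution_is_objective_minimizer():
    rng = np.random.default_rng(2)
    S = rng.normal(size=(15, 25))
    d = rng.normal(size=15)
    lam = 0.1
    x = TikhonovReconstructor(lam=lam).fit(S).transform(d)
    obj = lambda z: np.sum((S @ z - d) ** 2) + lam * np.sum(z**2)
    base = obj(x)
    for _ in range(10):
        pert = rng.normal(size=25)
        pert *= 1e-4 / np.linalg.norm(pert)
        assert obj(x + pert) > base


def test_shrinkage_and_residual_monotone_in_lambda():
    rng = np.random.default_rng(3)
    S = rng.normal(size=(20, 30))
    d = rng.normal(size=20)
    est = TikhonovReconstructor(lam=1.0).fit(S)
    norms, resids = [], []
    for lam in np.logspace(-4, 6, 16):
        x = est._solve(d, lam)
        norms.append(np.linalg.norm(x))
        resids.append(np.linalg.norm(S @ x - d))
    assert np.all(np.diff(norms) < 0)  # ||x|| -> 0 monotonically
    assert np.all(np.diff(resids) >= 0)  # residual non-decreasing
    assert norms[-1] < 1e-3 * norms[0]


def test_gcv_selects_from_grid(bench_model):
    est = TikhonovReconstructor(lam="auto").fit(bench_model.sensitivity)
    ph = es.make_case(1)
    dU, _ = bench_model.simulate(ph, snr_db=50, seed=0)
    lam = est.select_lambda(dU.values)
    assert lam in est.lambda_grid_
    est.transform(dU.values)
    assert est.lambda_ == lam


def test_gcv_regularizes_more_under_noise():
    """Noisy frames select lambda at least as large as noiseless, 8/10 seeds."""
    rng = np.random.default_rng(11)
    S = rng.normal(size=(60, 40)) @ np.diag(0.95 ** np.arange(40))
    x0 = rng.normal(size=40)
    d0 = S @ x0
    est = TikhonovReconstructor(lam="auto", grid_min=1e-8, grid_max=1.0).fit(S)
    lam0 = est.select_lambda(d0)
    wins = 0
    for seed in range(10):
        noise = np.random.default_rng(seed).normal(0, 0.05 * np.abs(d0).max(), 60)
        if est.select_lambda(d0 + noise) >= lam0:
            wins += 1
    assert wins >= 8


def test_degenerate_grid_rejected():
    with pytest.raises(ValueError):
        TikhonovReconstructor(lam="auto", grid_min=1.0, grid_max=0.1).fit(np.eye(4))
    with pytest.raises(ValueError):
        TikhonovReconstructor(lam="auto", n_grid=1).fit(np.eye(4))


def test_estimator_api_round_trip():
    est = TikhonovReconstructor(lam=0.5, n_grid=11)
    params = est.get_params()
    assert params["lam"] == 0.5 and params["n_grid"] == 11
    est2 = clone(est).set_params(lam="auto")
    assert est2.get_params()["lam"] == "auto"
    X = np.eye(6)
    out = est.fit(X).transform(np.ones(6))
    assert out.shape == (6,)
    stacked = est.transform(np.ones((3, 6)))
    assert stacked.shape == (3, 6)


# -- location compensation ----------------------------------------------


def test_location_compensation_weights():
    """Pixel at the centre keeps weight r; pixels at distance d get (r - d)."""
    grid = es.PixelGrid(side=5, radius=1.0)  # odd side -> exact centre pixel
    v = np.ones(grid.M)
    out = es.location_compensate(v, grid)
    centre = np.flatnonzero(grid.distances == 0.0)
    assert centre.size == 1
    assert out[centre[0]] == pytest.approx(1.0)  # scaled by r = 1 at d = 0
    assert np.allclose(out, 1.0 - grid.distances)


def test_location_compensation_linear_and_mask_preserving():
    grid = es.PixelGrid(side=16, radius=1.0)
    rng = np.random.default_rng(4)
    v = rng.normal(size=grid.M)
    a = es.location_compensate(3.0 * v, grid)
    b = 3.0 * es.location_compensate(v, grid)
    assert np.allclose(a, b, rtol=1e-12)
    img = es.location_compensate(grid.embed(v), grid)
    assert np.all(img[~grid.mask] == 0)
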