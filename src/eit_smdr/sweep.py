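"""Noise-sweep experiment harness.

Runs a grid of (phantom case x method x SNR x seed) reconstructions,
scores each against the ground truth, and aggregates mean CC/RE per
(method, SNR) — the robustness-versus-noise experiment.

To keep the noise comparison across SNR levels paired, one standard
normal noise direction is drawn per (case, seed) and only its amplitude
is scaled per SNR level (common random numbers).  The whole sweep is a
pure function of the seed list.
"""

from __future__ import annotations

import time
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .metrics import cc, normalize_truth_for_metrics, relative_error
from .model import ForwardModel, build_model
from .phantom import make_case, noise_std
from .protocol import VoltageFrame
from .recon import TikhonovReconstructor, location_compensate
from .smdr import SMDRReconstructor

__all__ = ["EvalReport", "run_noise_sweep"]

METHODS = ("tk", "smdr")


@dataclass(eq=False)
class EvalReport:
    """Per-run records and their (method, SNR) aggregation."""

    records: pd.DataFrame

    def summary(self) -> pd.DataFrame:
        """Mean CC/RE per (method, snr_db), recomputed from the records."""
        df = self.records.copy()
        df["snr_db"] = df["snr_db"].fillna(np.inf)  # noiseless sorts last
        out = (
            df.groupby(["method", "snr_db"], dropna=False)[["cc", "re"]]
            .mean()
            .reset_index()
            .sort_values(["method", "snr_db"])
            .reset_index(drop=True)
        )
        return out

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)

    def to_json(self, path) -> None:
        self.summary().to_json(path, orient="records", indent=2)


def _reconstruct(method: str, model: ForwardModel, dU: np.ndarray, lam, seed: int):
    """Returns (interior vector, lambda used, normalized?)."""
    if method == "tk":
        est = TikhonovReconstructor(lam=lam).fit(model.sensitivity)
        x = est.transform(dU)
        return x, est.lambda_, False
    if method == "smdr":
        est = SMDRReconstructor(lam=lam, random_state=seed).fit(model.sensitivity)
        res = est.reconstruct(dU)
        return res.image, res.lambda_, True
    raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")


def score_image(x: np.ndarray, truth_img: np.ndarray, model: ForwardModel, normalized: bool):
    """Location-compensate an interior vector and score it against truth."""
    grid = model.grid
    compensated = location_compensate(x, grid)
    truth = grid.extract(truth_img)
    truth_m, recon_m = normalize_truth_for_metrics(
        truth, compensated if not normalized else filterless_norm(compensated),
        recon_normalized=normalized,
    )
    return cc(recon_m, truth_m), relative_error(recon_m, truth_m)


def filterless_norm(v: np.ndarray) -> np.ndarray:
    """Rescale a nonnegative image to unit maximum (no-op when empty)."""
    m = v.max()
    return v / m if m > 0 else v


def run_noise_sweep(
    cases,
    methods=METHODS,
    snr_list=(None, 70, 65, 60, 55, 50, 40, 30),
    seeds=(0,),
    model: ForwardModel | None = None,
    lam="auto",
    n_elements: int = 2000,
    out_dir=None,
) -> EvalReport:
    """Simulate, reconstruct, and score every (case, method, SNR, seed).

    ``cases`` may mix library ids (1..6) and ``"random"``; random
    phantoms differ per seed.  ``snr_list`` may contain ``None`` for the
    noiseless entry.  Per-run failures are recorded (NaN scores) and the
    sweep continues.  With ``out_dir`` set, every reconstructed image is
    written as a 64x64 CSV and its path recorded.
    """
    if not len(cases) or not len(methods) or not len(snr_list) or not len(seeds):
        raise ValueError("cases, methods, snr_list, and seeds must be nonempty")
    if model is None:
        model = build_model(n_elements=n_elements)
    if out_dir is not None:
        from pathlib import Path

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)

    rows = []
    for seed in seeds:
        for case in cases:
            phantom = make_case(case, seed=seed)
            dU_clean, truth_img = model.simulate(phantom)
            case_tag = zlib.crc32(str(case).encode()) % (2**31)
            rng = np.random.default_rng(np.random.SeedSequence([int(seed), case_tag]))
            direction = rng.standard_normal(len(dU_clean))
            for snr in snr_list:
                if snr is None:
                    dU = dU_clean.values
                else:
                    dU = dU_clean.values + noise_std(dU_clean, snr) * direction
                for method in methods:
                    t0 = time.perf_counter()
                    try:
                        x, lam_used, normalized = _reconstruct(method, model, dU, lam, seed)
                        cc_val, re_val = score_image(x, truth_img, model, normalized)
                        err = ""
                    except Exception as exc:  # keep sweeping on per-run failure
                        x, lam_used = None, np.nan
                        cc_val, re_val = np.nan, np.nan
                        err = f"{type(exc).__name__}: {exc}"
                    runtime = time.perf_counter() - t0
                    image_path = ""
                    if out_dir is not None and x is not None:
                        name = f"{case}_{method}_{'inf' if snr is None else snr}_{seed}.csv"
                        np.savetxt(out_dir / name, model.grid.embed(x), delimiter=",")
                        image_path = str(out_dir / name)
                    rows.append(
                        dict(
                            case=str(case),
                            method=method,
                            snr_db=np.nan if snr is None else float(snr),
                            seed=int(seed),
                            lambda_used=lam_used,
                            cc=cc_val,
                            re=re_val,
                            runtime_s=runtime,
                            image_path=image_path,
                            error=err,
                        )
                    )
    return EvalReport(records=pd.DataFrame(rows))
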