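"""Streaming prediction with sample-specific error-in-variable intervals.

Applies a fitted calibration to a 5-s spectra series and emits, per
spectrum, the predicted property value, a dynamic prediction interval, the
constant ±RMSE_P band, the leverage of the spectrum in the calibration score
space, and an extrapolation flag.

The dynamic interval follows the error-in-variable form

    PrI = ŷ ± t_(df, 1-α/2) · sde · sqrt(1 + h + 1/n_cal)

so samples far from the model center (large leverage h) get wider intervals
and extrapolated predictions are visibly less certain than the constant
RMSE_P band suggests.
"""

from __future__ import annotations

from typing import TYPE_CHECKING

import numpy as np
import pandas as pd
from scipy import stats

from roastcal.containers import SpectraMatrix
from roastcal.pls import PLSModel, predict, scores_new
from roastcal.preprocess import average_time, baseline_correct

if TYPE_CHECKING:  # pragma: no cover
    from roastcal.pipeline import CalibrationBundle

__all__ = [
    "leverage_new",
    "degrees_of_freedom",
    "prediction_interval",
    "predict_stream",
]


def leverage_new(model: PLSModel, X_new: np.ndarray) -> np.ndarray:
    """Leverage h_ii = [t (TᵀT)⁻¹ tᵀ]_ii of new samples in score space.

    T is the calibration score matrix, t the scores of the samples to
    predict; the leverage measures the squared distance of a new spectrum
    from the calibration cloud along the model's latent variables.
    """
    T = model.scores
    G = T.T @ T
    if np.linalg.matrix_rank(G) < G.shape[0]:
        raise ValueError("singular score Gram matrix: collinear scores")
    t_new = scores_new(model, X_new)
    return np.einsum("ij,ij->i", t_new, np.linalg.solve(G, t_new.T).T)


def degrees_of_freedom(
    n_cal: int,
    rmse_fit: float | None = None,
    rmse_cv: float | None = None,
    n_components: int | None = None,
    method: str = "pseudo",
) -> float:
    """Degrees of freedom of the calibration residual variance.

    ``method="pseudo"`` uses cross-validation-based pseudo-degrees of
    freedom, df = n_cal (RMSE_fit/RMSE_CV)²: the residual variance corrected
    with this df equals the cross-validated MSE, so optimism of the fit error
    is removed without counting parameters of a latent-variable model.
    ``method="naive"`` falls back to df = n_cal - n_components - 1.
    The result is clamped to [1, n_cal - 1].
    """
    if method == "pseudo":
        if rmse_fit is None or rmse_cv is None or rmse_cv <= 0:
            raise ValueError("pseudo df needs rmse_fit and positive rmse_cv")
        df = n_cal * (rmse_fit / rmse_cv) ** 2
    elif method == "naive":
        if n_components is None:
            raise ValueError("naive df needs n_components")
        df = n_cal - n_components - 1
        if df <= 0:
            raise ValueError("non-positive degrees of freedom")
    else:
        raise ValueError(f"unknown df method {method!r}")
    return float(min(max(df, 1.0), n_cal - 1))


def prediction_interval(
    y_hat: np.ndarray,
    sde: float,
    df: float,
    leverage: np.ndarray,
    n_cal: int,
    alpha: float = 0.05,
) -> tuple[np.ndarray, np.ndarray]:
    """Error-in-variable prediction interval at confidence 1 - alpha."""
    if sde <= 0:
        raise ValueError("sde must be positive")
    if df < 1:
        raise ValueError("df must be >= 1")
    y_hat = np.asarray(y_hat, dtype=float)
    h = np.asarray(leverage, dtype=float)
    if np.any(h < 0):
        raise ValueError("leverages must be >= 0")
    tcrit = float(stats.t.ppf(1.0 - alpha / 2.0, df))
    half = tcrit * sde * np.sqrt(1.0 + h + 1.0 / n_cal)
    return y_hat - half, y_hat + half


def predict_stream(
    bundle: "CalibrationBundle",
    spectra: SpectraMatrix,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Predict a property time series from a streaming spectra matrix.

    The stream passes through the bundle's preprocessing state (time
    averaging if finer than the calibration resolution, baseline correction,
    channel restriction, L1 normalization, calibration-mean centering) and
    the masked PLS model.  Output columns: time_s, y_hat, pri_lower,
    pri_upper, rmsep_lower, rmsep_upper, leverage, extrapolated.  Spectra
    with zero total intensity on the retained channels (e.g. before volatile
    release) yield NaN predictions and are flagged.
    """
    state = bundle.state
    native = (float(np.median(np.diff(spectra.time_s)))
              if spectra.n_times > 1 else state.resolution_s)
    if native < state.resolution_s - 1e-9:
        spectra = average_time(spectra, state.resolution_s)
    spectra = baseline_correct(spectra, state.baseline_percentile)
    missing = np.setdiff1d(state.retained_channels, spectra.mz)
    if missing.size:
        raise ValueError(f"stream lacks retained channels {missing.tolist()}")
    cols = np.searchsorted(spectra.mz, state.retained_channels)
    X = spectra.intensity[:, cols]
    totals = np.abs(X).sum(axis=1)
    ok = totals > 0
    Xc = np.full_like(X, np.nan)
    Xc[ok] = X[ok] / totals[ok, None] - state.column_means[None, :]

    n = spectra.n_times
    y_hat = np.full(n, np.nan)
    h = np.full(n, np.nan)
    lo = np.full(n, np.nan)
    hi = np.full(n, np.nan)
    if ok.any():
        Xm = Xc[ok][:, bundle.mask]
        y_hat[ok] = predict(bundle.model, Xm)
        h[ok] = leverage_new(bundle.model, Xm)
        lo[ok], hi[ok] = prediction_interval(
            y_hat[ok], bundle.sde, bundle.df, h[ok], bundle.n_cal, alpha
        )
    extrapolated = ~ok | (y_hat < bundle.y_cal_min) | (y_hat > bundle.y_cal_max)
    return pd.DataFrame({
        "time_s": spectra.time_s,
        "y_hat": y_hat,
        "pri_lower": lo,
        "pri_upper": hi,
        "rmsep_lower": y_hat - bundle.rmse_p,
        "rmsep_upper": y_hat + bundle.rmse_p,
        "leverage": h,
        "extrapolated": extrapolated,
    })
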