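"""Multivariate figures of merit for inverse calibration models.

Accuracy metrics (RMSE, R², the external-set Q²F3 variant, RER, RPD),
net-analyte-signal sensitivity and selectivity, the analytical sensitivity
and its inverse, the full family of multivariate limits of detection
(3xRMSE_P, pseudounivariate, NAS-based, the IUPAC-consistent leverage range
and sample-specific values), limits of quantification, and residual
diagnostics.

Net analyte signal (NAS): with an unknown pure-analyte spectrum, the NAS of
a sample spectrum v is its orthogonal projection onto the direction of the
regression vector b, v* = b (bᵀb)⁻¹ bᵀ v.  Sensitivities, selectivities and
the NAS-based LOD all derive from it.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats

__all__ = [
    "FiguresOfMerit",
    "NASDecomposition",
    "rmse",
    "r2_calibration",
    "r2_prediction",
    "rer",
    "rpd",
    "sensitivity_b",
    "nas_decompose",
    "sensitivity_nas",
    "asen",
    "selectivity",
    "lod_3rmsep",
    "lod_pseudounivariate",
    "lod_nas",
    "extrapolated_leverages",
    "lod_range",
    "lod_sample_specific",
    "loq",
    "convert_brew_concentration",
    "residual_diagnostics",
    "compute_figures_of_merit",
]

logger = logging.getLogger(__name__)


def rmse(y_hat: np.ndarray, y: np.ndarray) -> float:
    """Root mean square error of fit, cross-validation or prediction."""
    y_hat = np.asarray(y_hat, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if y_hat.size != y.size or y.size < 1:
        raise ValueError("y_hat and y must be equal-length, non-empty")
    return float(np.sqrt(np.mean((y_hat - y) ** 2)))


def r2_calibration(y_hat: np.ndarray, y: np.ndarray) -> float:
    """Explained variance: 1 - RSS/TSS about the mean of the measured values."""
    y_hat = np.asarray(y_hat, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if y.size < 2:
        raise ValueError("need at least 2 samples for R^2")
    tss = float(((y - y.mean()) ** 2).sum())
    if tss <= 0:
        raise ValueError("zero total sum of squares: R^2 undefined")
    return 1.0 - float(((y_hat - y) ** 2).sum()) / tss


def r2_prediction(
    y_hat_ext: np.ndarray, y_ext: np.ndarray, y_cal: np.ndarray
) -> float:
    """Explained variance in prediction (the Q²F3 form).

    1 - (RSS_ext/n_ext) / (TSS_cal/n_cal), with the total sum of squares
    taken about the *calibration* mean — insensitive to how the external
    samples happen to be distributed over the calibrated range.
    """
    y_hat_ext = np.asarray(y_hat_ext, dtype=float).ravel()
    y_ext = np.asarray(y_ext, dtype=float).ravel()
    y_cal = np.asarray(y_cal, dtype=float).ravel()
    if y_ext.size < 1 or y_cal.size < 2:
        raise ValueError("need >= 1 external and >= 2 calibration samples")
    tss_cal = float(((y_cal - y_cal.mean()) ** 2).sum())
    if tss_cal <= 0:
        raise ValueError("zero calibration total sum of squares")
    rss = float(((y_hat_ext - y_ext) ** 2).sum())
    return 1.0 - (rss / y_ext.size) / (tss_cal / y_cal.size)


def rer(y_ext: np.ndarray, rmse_p: float) -> float:
    """Range-error ratio: external response range over RMSE_P (> 10 is 'good')."""
    y_ext = np.asarray(y_ext, dtype=float).ravel()
    if y_ext.size < 2:
        raise ValueError("RER needs at least 2 external samples")
    if rmse_p <= 0:
        raise ValueError("RER needs a positive RMSE_P")
    return float((y_ext.max() - y_ext.min()) / rmse_p)


def rpd(y_ext: np.ndarray, rmse_p: float) -> float:
    """Residual prediction deviation: SD of the external responses over RMSE_P.

    Reported for information only — it carries the same information as R²
    and depends on the response distribution.
    """
    y_ext = np.asarray(y_ext, dtype=float).ravel()
    if y_ext.size < 2:
        raise ValueError("RPD needs at least 2 external samples")
    sd = float(y_ext.std(ddof=1))
    if sd <= 0:
        raise ValueError("zero external variance: RPD undefined")
    return sd / rmse_p


def sensitivity_b(b: np.ndarray) -> float:
    """Sensitivity from the regression vector: SEN_b = 1/||b||_2."""
    b = np.asarray(b, dtype=float).ravel()
    nb = float(np.linalg.norm(b))
    if nb <= 0:
        raise ValueError("zero regression vector")
    return 1.0 / nb


@dataclass
class NASDecomposition:
    """Per-sample net analyte signal vectors and their norms."""

    nas: np.ndarray        # (n, p): v* rows, each parallel to b
    nas_norms: np.ndarray  # (n,)
    v_norms: np.ndarray    # (n,): norms of the input spectra


def nas_decompose(b: np.ndarray, X: np.ndarray) -> NASDecomposition:
    """Project each spectrum onto the regression-vector direction.

    v* = b (bᵀb)⁻¹ bᵀ v per row of X; the projection is idempotent and
    norm-contracting.
    """
    b = np.asarray(b, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    bb = float(b @ b)
    if bb <= 0:
        raise ValueError("zero regression vector")
    coef = (X @ b) / bb
    nas = coef[:, None] * b[None, :]
    return NASDecomposition(
        nas=nas,
        nas_norms=np.abs(coef) * np.linalg.norm(b),
        v_norms=np.linalg.norm(X, axis=1),
    )


def sensitivity_nas(nas: NASDecomposition, c: np.ndarray) -> float:
    """NAS-based sensitivity: median over samples of ||v*_i / c_i||.

    Samples with a zero reference value are skipped with a warning.
    """
    c = np.asarray(c, dtype=float).ravel()
    ok = c != 0
    if not ok.all():
        logger.warning("sensitivity_nas: skipping %d samples with zero "
                       "reference value", int((~ok).sum()))
    if not ok.any():
        raise ValueError("all reference values are zero")
    return float(np.median(nas.nas_norms[ok] / np.abs(c[ok])))


def asen(sen: float, delta_x: float) -> tuple[float, float]:
    """Analytical sensitivity ASEN = SEN/δx and its inverse.

    The inverse is the smallest property difference distinguishable when
    instrumental random noise is the only interference; it carries the
    property's units (e.g. GA-eq mg/L for the FC value).
    """
    if delta_x <= 0:
        raise ValueError("delta_x must be positive")
    a = sen / delta_x
    return a, 1.0 / a


def selectivity(nas: NASDecomposition, aggregate: str = "median") -> float:
    """Share of each spectrum captured by the NAS, in percent.

    Per sample 100 * ||v*||/||v||, aggregated over the calibration samples by
    the median (configurable to the mean); zero-norm spectra are skipped.
    """
    ok = nas.v_norms > 0
    if not ok.any():
        raise ValueError("all spectra have zero norm")
    if not ok.all():
        logger.warning("selectivity: skipping %d zero-norm spectra",
                       int((~ok).sum()))
    per = 100.0 * nas.nas_norms[ok] / nas.v_norms[ok]
    return float(np.median(per) if aggregate == "median" else per.mean())


def lod_3rmsep(rmse_p: float) -> float:
    """Limit of detection as 3 x RMSE_P."""
    if rmse_p < 0:
        raise ValueError("RMSE_P must be >= 0")
    return 3.0 * rmse_p


def lod_pseudounivariate(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Pseudounivariate LOD from the measured-vs-predicted regression.

    LOD_pu = 3.3 * m_pu * sqrt((1 + h0min + 1/n_cal) * s²_r) with m_pu the
    slope of measured-versus-predicted, s²_r the variance of its residuals
    and h0min the minimum (zero-property extrapolated) leverage
    h0min = ȳ² / Σ(y_i - ȳ)².
    """
    y = np.asarray(y, dtype=float).ravel()
    y_hat = np.asarray(y_hat, dtype=float).ravel()
    n = y.size
    if n < 3:
        raise ValueError("need at least 3 calibration samples")
    if np.ptp(y_hat) <= 0:
        raise ValueError("degenerate regression: constant predictions")
    slope, intercept = np.polyfit(y_hat, y, 1)
    resid = y - (slope * y_hat + intercept)
    s2r = float((resid**2).sum() / (n - 2))
    ssy = float(((y - y.mean()) ** 2).sum())
    if ssy <= 0:
        raise ValueError("degenerate regression: constant measured values")
    h0min = float(y.mean() ** 2 / ssy)
    return float(3.3 * slope * np.sqrt((1.0 + h0min + 1.0 / n) * s2r))


def lod_nas(delta: float, sen_nas: float) -> float:
    """NAS-based LOD: 3 times the instrumental noise over the net sensitivity."""
    if sen_nas <= 0:
        raise ValueError("net sensitivity must be positive")
    return 3.0 * delta / sen_nas


def extrapolated_leverages(y_cal: np.ndarray) -> np.ndarray:
    """Zero-property extrapolated leverage of each calibration sample.

    h0_i = (ȳ² + (y_i - ȳ)²) / Σ(y_j - ȳ)², which reduces to the minimum
    leverage ȳ²/Σ(y - ȳ)² for a sample sitting at the calibration mean.
    """
    y = np.asarray(y_cal, dtype=float).ravel()
    ss = float(((y - y.mean()) ** 2).sum())
    if ss <= 0:
        raise ValueError("zero spread in calibration values")
    return (y.mean() ** 2 + (y - y.mean()) ** 2) / ss


def _lod_at_leverage(sen: float, var_x: float, var_ycal: float,
                     h0: np.ndarray | float) -> np.ndarray | float:
    return 3.3 * np.sqrt(var_x / sen**2 * (1.0 + np.asarray(h0))
                         + np.asarray(h0) * var_ycal)


def lod_range(
    sen: float, var_x: float, var_ycal: float, h0min: float, h0max: float
) -> tuple[float, float]:
    """IUPAC-consistent LOD range evaluated at the extreme leverages.

    LOD(h0) = 3.3 * sqrt(SEN⁻² var(x) + h0 SEN⁻² var(x) + h0 var(y_cal)),
    where var(x) is the instrumental-signal noise variance and var(y_cal)
    the variance of the calibration reference-value error.  Signals above
    LOD_max are detected, below LOD_min not detected; in between the
    sample-specific LOD decides.
    """
    if sen <= 0:
        raise ValueError("sensitivity must be positive")
    if var_x < 0 or var_ycal < 0:
        raise ValueError("variances must be >= 0")
    if h0min > h0max:
        raise ValueError("h0min must not exceed h0max")
    return (float(_lod_at_leverage(sen, var_x, var_ycal, h0min)),
            float(_lod_at_leverage(sen, var_x, var_ycal, h0max)))


def lod_sample_specific(
    sen: float, var_x: float, var_ycal: float, leverages: np.ndarray
) -> tuple[np.ndarray, float]:
    """Sample-specific LODs at each sample's leverage, plus their median."""
    h = np.asarray(leverages, dtype=float).ravel()
    if np.any(h < 0):
        raise ValueError("leverages must be >= 0")
    vals = np.asarray(_lod_at_leverage(sen, var_x, var_ycal, h), dtype=float)
    return vals, float(np.median(vals))


def loq(lod: float) -> float:
    """Limit of quantification: 3 x LOD (95% confidence, 10% relative error)."""
    if lod < 0:
        raise ValueError("LOD must be >= 0")
    return 3.0 * lod


def convert_brew_concentration(
    c_mg_per_l: float, coffee_dose_g: float = 12.0, water_volume_ml: float = 200.0
) -> float:
    """Convert a brew concentration (GA-eq mg/L) to g per kg of ground coffee.

    Default brew recipe: 12 g coffee on 200 mL water, so
    c * 0.2 L / 12 g in mg/g ≡ g/kg.
    """
    if coffee_dose_g <= 0 or water_volume_ml <= 0:
        raise ValueError("dose and volume must be positive")
    return c_mg_per_l * (water_volume_ml / 1000.0) / coffee_dose_g


def _poly_r2(x: np.ndarray, r: np.ndarray, degree: int) -> float:
    coef = np.polyfit(x, r, degree)
    fit = np.polyval(coef, x)
    sst = float(((r - r.mean()) ** 2).sum())
    if sst <= 0:
        return 0.0
    return 1.0 - float(((r - fit) ** 2).sum()) / sst


def residual_diagnostics(
    residuals: np.ndarray,
    predicted: np.ndarray,
    n_permutations: int = 5000,
    seed: int = 0,
) -> dict:
    """Normality and trend diagnostics of regression residuals.

    Shapiro-Wilk p-value plus permutation p-values for a first- and
    second-degree polynomial trend of the residuals versus the predicted
    values (test statistic: R² gain of the polynomial fit; the residual order
    is permuted).  Constant residuals leave the normality test undefined.
    """
    r = np.asarray(residuals, dtype=float).ravel()
    x = np.asarray(predicted, dtype=float).ravel()
    if r.size < 3 or r.size != x.size:
        raise ValueError("need >= 3 residuals matched to predictions")
    out: dict = {"n": int(r.size), "n_permutations": int(n_permutations)}
    if np.ptp(r) <= 0:
        out["shapiro_p"] = float("nan")
        out["note"] = "constant residuals: normality test undefined"
        out["perm_p_deg1"] = float("nan")
        out["perm_p_deg2"] = float("nan")
        return out
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out["shapiro_p"] = float(stats.shapiro(r).pvalue)
    rng = np.random.default_rng(seed)
    for degree in (1, 2):
        obs = _poly_r2(x, r, degree)
        hits = 0
        for _ in range(n_permutations):
            if _poly_r2(x, rng.permutation(r), degree) >= obs:
                hits += 1
        out[f"perm_p_deg{degree}"] = (hits + 1.0) / (n_permutations + 1.0)
    return out


@dataclass
class FiguresOfMerit:
    """Complete figures-of-merit record for one calibration model.

    RMSE/R² triples for fit, cross-validation and external prediction;
    range-error ratio and (informational) residual prediction deviation;
    regression-vector and NAS sensitivities with the analytical sensitivity
    pair; selectivity in percent; the LOD family and the corresponding LOQs
    (always exactly 3 x LOD).
    """

    rmse_fit: float
    rmse_cv: float
    rmse_p: float
    r2_fit: float
    r2_cv: float
    r2_p: float
    rer: float
    rpd_informational: float
    rel_rmse_p_range: float
    rel_rmse_p_mean: float
    sen_b: float
    sen_nas: float
    asen: float
    asen_inverse: float
    sel_percent: float
    lod_pu: float
    lod_3rmsep: float
    lod_nas: float
    lod_min: float
    lod_max: float
    lod_ss_median: float
    loq_pu: float
    loq_3rmsep: float
    loq_nas: float
    loq_ss_median: float
    n_cal: int
    n_ext: int

    def to_dict(self) -> dict:
        return asdict(self)


def compute_figures_of_merit(
    y_cal: np.ndarray,
    y_hat_cal: np.ndarray,
    y_ext: np.ndarray,
    y_hat_ext: np.ndarray,
    b: np.ndarray,
    X_cal: np.ndarray,
    delta_x: float,
    rmse_cv: float = float("nan"),
    r2_cv: float = float("nan"),
    var_ycal_err: float = 0.0,
    sel_aggregate: str = "median",
) -> FiguresOfMerit:
    """Assemble the full figures-of-merit record from a fitted model.

    ``X_cal`` are the centered calibration descriptors restricted to the
    model's variables; ``delta_x`` is the scalar instrumental noise on the
    descriptor scale (one noise estimate is used across ASEN, the NAS LOD
    and the LOD range, with var(x) = delta_x²); ``var_ycal_err`` is the
    variance of the reference-value error (0 for error-free references).
    """
    y_cal = np.asarray(y_cal, dtype=float).ravel()
    y_ext = np.asarray(y_ext, dtype=float).ravel()
    rmse_p = rmse(y_hat_ext, y_ext)
    nas = nas_decompose(b, X_cal)
    sen_b_val = sensitivity_b(b)
    sen_nas_val = sensitivity_nas(nas, y_cal)
    asen_val, asen_inv = asen(sen_b_val, delta_x)
    h0 = extrapolated_leverages(y_cal)
    lmin, lmax = lod_range(sen_b_val, delta_x**2, var_ycal_err,
                           float(h0.min()), float(h0.max()))
    _, lss = lod_sample_specific(sen_b_val, delta_x**2, var_ycal_err, h0)
    l_pu = lod_pseudounivariate(y_cal, y_hat_cal)
    l_3r = lod_3rmsep(rmse_p)
    l_nas = lod_nas(delta_x, sen_nas_val)
    y_cal_range = float(y_cal.max() - y_cal.min())
    return FiguresOfMerit(
        rmse_fit=rmse(y_hat_cal, y_cal),
        rmse_cv=float(rmse_cv),
        rmse_p=rmse_p,
        r2_fit=r2_calibration(y_hat_cal, y_cal),
        r2_cv=float(r2_cv),
        r2_p=r2_prediction(y_hat_ext, y_ext, y_cal),
        rer=rer(y_ext, rmse_p),
        rpd_informational=rpd(y_ext, rmse_p),
        rel_rmse_p_range=rmse_p / y_cal_range if y_cal_range > 0 else float("nan"),
        rel_rmse_p_mean=rmse_p / float(np.mean(y_cal)),
        sen_b=sen_b_val,
        sen_nas=sen_nas_val,
        asen=asen_val,
        asen_inverse=asen_inv,
        sel_percent=selectivity(nas, aggregate=sel_aggregate),
        lod_pu=l_pu,
        lod_3rmsep=l_3r,
        lod_nas=l_nas,
        lod_min=lmin,
        lod_max=lmax,
        lod_ss_median=lss,
        loq_pu=loq(l_pu),
        loq_3rmsep=loq(l_3r),
        loq_nas=loq(l_nas),
        loq_ss_median=loq(lss),
        n_cal=int(y_cal.size),
        n_ext=int(y_ext.size),
    )
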