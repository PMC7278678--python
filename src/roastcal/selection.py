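"""Data splitting, Monte Carlo cross-validation and CARS variable selection.

All randomness flows through explicit integer seeds; every stochastic
operation reruns bit-identically under the same seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from roastcal.pls import _simpls, fit_pls

__all__ = [
    "CVResult",
    "CARSResult",
    "split_calibration_external",
    "monte_carlo_cv",
    "select_n_components",
    "cars_select",
]

logger = logging.getLogger(__name__)


def split_calibration_external(
    records: list, seed: int, calibration_fraction: float = 0.8
) -> tuple[list, list]:
    """Random roast-level split into calibration and external validation sets.

    The calibration set gets ``floor(calibration_fraction * n)`` roasts (4:1
    by default, so 84 roasts give 67 calibration / 17 external); the split is
    reproducible under the seed and never divides a roast's spectra between
    the two sets.
    """
    n = len(records)
    if n < 5:
        raise ValueError(f"need at least 5 records to split 4:1, got {n}")
    n_cal = int(math.floor(calibration_fraction * n))
    perm = np.random.default_rng(seed).permutation(n)
    cal_idx = np.sort(perm[:n_cal])
    ext_idx = np.sort(perm[n_cal:])
    return [records[i] for i in cal_idx], [records[i] for i in ext_idx]


@dataclass
class CVResult:
    """Fit and Monte Carlo cross-validation error curves over component counts."""

    components: np.ndarray
    rmse_fit: np.ndarray
    rmse_cv: np.ndarray
    r2_fit: np.ndarray
    r2_cv: np.ndarray
    n_repeats: int
    seed: int


def monte_carlo_cv(
    X: np.ndarray,
    y: np.ndarray,
    max_components: int = 20,
    frac_train: float = 0.8,
    n_repeats: int = 1000,
    seed: int = 0,
) -> CVResult:
    """Monte Carlo cross-validation of PLS over 1..max_components.

    Each repeat fits on a random 80% of the calibration samples (re-centered
    per subset) and predicts the held-out 20%; squared errors are pooled over
    all repeats before taking the root, so the returned RMSE_CV curve is a
    single pooled estimate per component count rather than an average of
    per-repeat RMSEs.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    n_train = int(math.floor(frac_train * n))
    n_test = n - n_train
    if n_test < 1 or n_train < 2:
        raise ValueError("too few samples for the requested training fraction")
    A = min(max_components, n_train - 1, p)
    if A < max_components:
        logger.warning(
            "monte_carlo_cv: truncating max components from %d to %d",
            max_components, A,
        )
    y_mean_full = y.mean()

    # fit curve on the full calibration set
    model = fit_pls(X, y, A, center_x=True, strict=False)
    resid_fit = y[:, None] - ((X - model.x_mean) @ model.coef_path + model.y_mean)
    rmse_fit = np.sqrt((resid_fit**2).mean(axis=0))
    tss = float(((y - y_mean_full) ** 2).sum())
    if tss <= 0:
        raise ValueError("zero total sum of squares in y")
    r2_fit = 1.0 - (resid_fit**2).sum(axis=0) / tss

    rng = np.random.default_rng(seed)
    sse = np.zeros(A)
    tss_acc = 0.0
    count = 0
    for _ in range(n_repeats):
        perm = rng.permutation(n)
        tr, te = perm[:n_train], perm[n_train:]
        xm = X[tr].mean(axis=0)
        ym = y[tr].mean()
        _, _, _, _, B, _ = _simpls(X[tr] - xm, y[tr] - ym, A, strict=False)
        pred = (X[te] - xm) @ B + ym
        err = pred - y[te][:, None]
        sse += (err**2).sum(axis=0)
        tss_acc += float(((y[te] - y_mean_full) ** 2).sum())
        count += n_test
    rmse_cv = np.sqrt(sse / count)
    r2_cv = 1.0 - sse / tss_acc
    return CVResult(
        components=np.arange(1, A + 1),
        rmse_fit=rmse_fit, rmse_cv=rmse_cv, r2_fit=r2_fit, r2_cv=r2_cv,
        n_repeats=n_repeats, seed=seed,
    )


def select_n_components(cv: CVResult, tie_tol: float = 1e-8) -> int:
    """Component count at the minimum RMSE_CV, ties broken toward fewer.

    Curves that differ from the minimum by less than ``tie_tol`` times the
    curve's spread count as ties, so exact-rank (noise-free) data selects the
    true rank rather than an arbitrary larger count.
    """
    r = np.asarray(cv.rmse_cv, dtype=float)
    thr = r.min() + tie_tol * (r.max() - r.min())
    best = int(np.flatnonzero(r <= thr)[0])
    if best == r.size - 1 and r.size > 1:
        logger.warning("select_n_components: RMSE_CV still decreasing at the "
                       "maximum component count (possible overfit)")
    return int(cv.components[best])


@dataclass
class CARSResult:
    """Outcome of repeated competitive adaptive reweighted sampling.

    ``mask`` marks the variables retained in the majority of repetitions;
    ``n_components`` is re-selected by Monte Carlo CV on the masked data.
    ``masks_per_repetition`` / ``lv_per_repetition`` feed the mean (SD)
    summary reported alongside the final model.
    """

    mask: np.ndarray                      # (p,) bool
    n_components: int
    rmse_trajectory: np.ndarray           # per-iteration RMSE_CV, 1st repetition
    masks_per_repetition: np.ndarray      # (reps, p) bool
    lv_per_repetition: np.ndarray         # (reps,)
    seed: int

    @property
    def mask_size_mean(self) -> float:
        return float(self.masks_per_repetition.sum(axis=1).mean())

    @property
    def mask_size_sd(self) -> float:
        return float(self.masks_per_repetition.sum(axis=1).std(ddof=1))

    @property
    def lv_mean(self) -> float:
        return float(self.lv_per_repetition.mean())

    @property
    def lv_sd(self) -> float:
        return float(self.lv_per_repetition.std(ddof=1))


def _kfold_rmse_curve(
    X: np.ndarray, y: np.ndarray, max_components: int, n_folds: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Pooled k-fold RMSE_CV per component count 1..A."""
    n, p = X.shape
    folds = rng.permutation(n) % n_folds
    A = min(max_components, n - int(np.ceil(n / n_folds)) - 1, p)
    A = max(A, 1)
    sse = np.zeros(A)
    for f in range(n_folds):
        te = folds == f
        tr = ~te
        if te.sum() == 0 or tr.sum() < 2:
            continue
        xm = X[tr].mean(axis=0)
        ym = y[tr].mean()
        _, _, _, _, B, _ = _simpls(X[tr] - xm, y[tr] - ym, A, strict=False)
        err = (X[te] - xm) @ B + ym - y[te][:, None]
        sse += (err**2).sum(axis=0)
    return np.sqrt(sse / n)


def _best_component(curve: np.ndarray, tie_tol: float = 1e-8) -> int:
    thr = curve.min() + tie_tol * (curve.max() - curve.min())
    return int(np.flatnonzero(curve <= thr)[0]) + 1


def _cars_once(
    X: np.ndarray, y: np.ndarray, rng: np.random.Generator,
    n_cars_runs: int, max_components: int, frac_samples: float, n_folds: int,
) -> tuple[np.ndarray, int, np.ndarray]:
    """One CARS repetition: returns (best mask indices, best LV, RMSE trajectory)."""
    n, p = X.shape
    current = np.arange(p)
    # exponentially decreasing fraction of variables: from all p down to 2
    a_edf = (p / 2.0) ** (1.0 / (n_cars_runs - 1))
    k_edf = math.log(p / 2.0) / (n_cars_runs - 1)
    best_rmse = math.inf
    best_mask = current
    best_lv = 1
    traj = np.empty(n_cars_runs)
    for i in range(1, n_cars_runs + 1):
        rows = rng.permutation(n)[: max(4, int(round(frac_samples * n)))]
        A = max(1, min(max_components, rows.size - 1, current.size))
        sub = fit_pls(X[np.ix_(rows, current)], y[rows], A,
                      center_x=True, strict=False)
        w = np.abs(sub.b)
        if w.sum() <= 0:
            w = np.ones_like(w)
        n_keep = min(current.size, max(2, int(round(a_edf * math.exp(-k_edf * i) * p))))
        # enforced selection of the strongest variables ...
        order = np.argsort(w)[::-1][:n_keep]
        forced = current[order]
        wf = w[order] / w[order].sum()
        # ... then adaptive reweighted sampling among them
        picks = rng.choice(forced, size=n_keep, replace=True, p=wf)
        new = np.unique(picks)
        if new.size < 2:
            new = np.sort(forced[:2])
        curve = _kfold_rmse_curve(X[:, new], y, max_components, n_folds, rng)
        lv = _best_component(curve)
        traj[i - 1] = curve[lv - 1]
        if curve[lv - 1] < best_rmse:
            best_rmse, best_mask, best_lv = float(curve[lv - 1]), new, lv
        current = new
    return best_mask, best_lv, traj


def cars_select(
    X: np.ndarray,
    y: np.ndarray,
    n_cars_runs: int = 50,
    n_repetitions: int = 100,
    max_components: int = 10,
    frac_samples: float = 0.8,
    n_folds: int = 5,
    seed: int = 0,
    final_cv_repeats: int = 200,
) -> CARSResult:
    """Competitive adaptive reweighted sampling variable selection.

    Survival-of-the-fittest elimination of spectral variables: in each of
    ``n_cars_runs`` Monte Carlo iterations a PLS model is fitted on a random
    80% of the calibration samples, variables are ranked by |b|, an
    exponentially shrinking fraction is force-retained, and adaptive
    reweighted sampling (a |b|-weighted bootstrap) decides the survivors.
    Each iteration's candidate subset is scored by k-fold RMSE_CV and the
    best subset of the run wins.  The whole procedure is repeated
    ``n_repetitions`` times; the final mask keeps the variables retained in
    the majority of repetitions and the component count is re-selected by
    Monte Carlo CV on the masked data.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if p < 2:
        raise ValueError("CARS needs at least 2 variables")
    root = np.random.default_rng(seed)
    masks = np.zeros((n_repetitions, p), dtype=bool)
    lvs = np.zeros(n_repetitions, dtype=int)
    traj0 = None
    for rep in range(n_repetitions):
        rng = np.random.default_rng(root.integers(0, 2**31))
        mask_idx, lv, traj = _cars_once(
            X, y, rng, n_cars_runs, max_components, frac_samples, n_folds
        )
        masks[rep, mask_idx] = True
        lvs[rep] = lv
        if traj0 is None:
            traj0 = traj
    votes = masks.sum(axis=0)
    final = votes > n_repetitions / 2.0
    if not final.any():
        raise ValueError("CARS eliminated every variable (no majority survivor)")
    cv = monte_carlo_cv(
        X[:, final], y, max_components=max_components,
        n_repeats=final_cv_repeats, seed=int(root.integers(0, 2**31)),
    )
    n_comp = select_n_components(cv)
    return CARSResult(
        mask=final, n_components=n_comp, rmse_trajectory=traj0,
        masks_per_repetition=masks, lv_per_repetition=lvs, seed=seed,
    )
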