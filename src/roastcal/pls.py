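"""PLS1 regression engine (SIMPLS).

Single-response partial least squares computed with the SIMPLS deflation:
successive weight vectors maximize covariance with the response under
orthogonality of the score vectors.  The engine exposes everything the
figures of merit consume: weights, loadings, the calibration score matrix T
and the regression coefficient vector b, plus the full coefficient path over
1..A components (used heavily by cross-validation).

Conventions
-----------
* X is expected column-centered (the preprocessing state is the single
  source of truth for X centering; ``center_x=True`` is available for
  internal resampling where subsets must be re-centered).
* y is centered inside the model and ``y_mean`` is stored.
* Score columns are orthonormal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["PLSModel", "fit_pls", "predict", "scores_new"]


@dataclass
class PLSModel:
    """Fitted PLS1 model.

    ``b`` is the regression vector at ``n_components`` latent variables so
    that ``y_hat = (X - x_mean) @ b + y_mean``; ``coef_path[:, a-1]`` holds
    the coefficient vector of the a-component submodel.
    """

    weights: np.ndarray          # R (p, A): X @ R gives scores
    x_loadings: np.ndarray       # P (p, A)
    y_loadings: np.ndarray       # q (A,)
    scores: np.ndarray           # T (n, A), orthonormal columns
    b: np.ndarray                # (p,)
    coef_path: np.ndarray        # (p, A)
    n_components: int
    y_mean: float
    x_mean: np.ndarray           # (p,), zeros unless center_x was requested
    variable_mask: np.ndarray | None = None

    @property
    def n_variables(self) -> int:
        return self.b.size


def _simpls(
    X: np.ndarray, y: np.ndarray, n_components: int, strict: bool
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray, int]:
    """Core SIMPLS loop on centered data.

    Returns (R, P, q, T, B, a_eff).  When the data rank is exhausted before
    ``n_components`` and ``strict`` is False, the coefficient path is padded
    with the last achievable coefficient vector (adding components beyond the
    rank cannot change predictions); with ``strict`` True a ValueError names
    the achievable maximum.
    """
    n, p = X.shape
    A = n_components
    S = X.T @ y
    R = np.zeros((p, A))
    P = np.zeros((p, A))
    q = np.zeros(A)
    T = np.zeros((n, A))
    V = np.zeros((p, A))
    B = np.zeros((p, A))
    t_ref = 0.0
    a_eff = 0
    for a in range(A):
        r = S.copy()
        t = X @ r
        tn = float(np.linalg.norm(t))
        if a == 0:
            t_ref = tn
        if tn <= 1e-12 * max(t_ref, 1e-300):
            break
        t /= tn
        r /= tn
        p_a = X.T @ t
        q_a = float(y @ t)
        v = p_a.copy()
        if a > 0:
            v -= V[:, :a] @ (V[:, :a].T @ p_a)
        vn = float(np.linalg.norm(v))
        if vn <= 1e-12 * max(float(np.linalg.norm(p_a)), 1e-300):
            break
        v /= vn
        S = S - v * float(v @ S)
        R[:, a], P[:, a], q[a], T[:, a], V[:, a] = r, p_a, q_a, t, v
        B[:, a] = (B[:, a - 1] if a else 0.0) + q_a * r
        a_eff = a + 1
    if a_eff < A:
        if strict:
            raise ValueError(
                f"requested {A} components but the data supports at most {a_eff}"
            )
        for a in range(a_eff, A):
            R[:, a] = 0.0
            B[:, a] = B[:, a_eff - 1] if a_eff else 0.0
    return R, P, q, T, B, a_eff


def fit_pls(
    X: np.ndarray,
    y: np.ndarray,
    n_components: int,
    center_x: bool = False,
    strict: bool = True,
) -> PLSModel:
    """Fit a PLS1 model with ``n_components`` latent variables.

    The fit is fully deterministic.  ``X`` must be centered unless
    ``center_x`` is set; y is centered internally.  Raises when
    ``n_components`` exceeds what the data rank supports (``strict``).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.size != n:
        raise ValueError("X and y have inconsistent sample counts")
    if not 1 <= n_components <= min(n - 1, p):
        raise ValueError(
            f"n_components must be in [1, {min(n - 1, p)}], got {n_components}"
        )
    x_mean = X.mean(axis=0) if center_x else np.zeros(p)
    y_mean = float(y.mean())
    R, P, q, T, B, a_eff = _simpls(X - x_mean, y - y_mean, n_components, strict)
    return PLSModel(
        weights=R, x_loadings=P, y_loadings=q, scores=T,
        b=B[:, n_components - 1].copy(), coef_path=B,
        n_components=n_components, y_mean=y_mean, x_mean=x_mean,
    )


def _check_width(model: PLSModel, X_new: np.ndarray) -> np.ndarray:
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != model.n_variables:
        raise ValueError(
            f"channel mismatch: model has {model.n_variables} variables, "
            f"input has {X_new.shape[1]}"
        )
    return X_new


def predict(model: PLSModel, X_new: np.ndarray) -> np.ndarray:
    """Predict the property for preprocessed (centered, masked) spectra."""
    X_new = _check_width(model, X_new)
    return (X_new - model.x_mean) @ model.b + model.y_mean


def scores_new(model: PLSModel, X_new: np.ndarray) -> np.ndarray:
    """Project new spectra onto the model's latent variables.

    For the calibration matrix itself this reproduces the calibration score
    matrix T; a zero (centered) row maps to zero scores.
    """
    X_new = _check_width(model, X_new)
    return (X_new - model.x_mean) @ model.weights
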