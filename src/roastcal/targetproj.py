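"""Target-projection loadings and their cross-model correlation structure.

Target projection condenses the property-relevant variation of the spectra
onto a single latent direction: the TP score is the (normalized) predicted
response, and the TP loading of a channel is its covariance with that score.
Unlike correlation-based importance measures, TP loadings keep the signal
height, so dominant channels dominate the loading vector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from roastcal.pls import PLSModel

__all__ = ["TPLoadings", "tp_loadings", "tp_correlation_matrix"]


@dataclass
class TPLoadings:
    """Signed target-projection loading per retained channel of one model."""

    channels: np.ndarray
    loadings: np.ndarray
    model_id: str = ""

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=int)
        self.loadings = np.asarray(self.loadings, dtype=float)
        if self.channels.size != self.loadings.size:
            raise ValueError("channels and loadings must have equal length")
        if self.channels.size and not np.any(self.loadings):
            raise ValueError("all-zero TP loadings")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"mz": self.channels, "tp_loading": self.loadings})


def tp_loadings(
    model: PLSModel, X_cal: np.ndarray, channels: np.ndarray | None = None,
    model_id: str = "",
) -> TPLoadings:
    """Target-projection loadings of a fitted model on its calibration data.

    TP score t = X b/||b||; loadings p = Xᵀ t/(tᵀ t).  A channel positively
    covarying with the predicted property gets a positive loading.
    """
    X = np.atleast_2d(np.asarray(X_cal, dtype=float)) - model.x_mean
    b = model.b
    nb = float(np.linalg.norm(b))
    if nb <= 0:
        raise ValueError("zero regression vector")
    t = X @ (b / nb)
    tt = float(t @ t)
    if tt <= 0:
        raise ValueError("degenerate TP score (zero variance)")
    p = X.T @ t / tt
    if channels is None:
        channels = np.arange(1, p.size + 1)
    return TPLoadings(channels=np.asarray(channels), loadings=p, model_id=model_id)


def tp_correlation_matrix(
    loadings: list[TPLoadings],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlation of TP loading vectors across models.

    Vectors are aligned on the union of the models' channel sets, with zeros
    filled in for channels a model does not select.  Returns the symmetric
    matrix of Pearson r and the matrix of -log10(p) from the exact
    t-transform (values above 1.301 are significant at alpha = 0.05).
    """
    if len(loadings) < 2:
        raise ValueError("need at least 2 loading vectors")
    union = np.unique(np.concatenate([l.channels for l in loadings]))
    mat = np.zeros((len(loadings), union.size))
    ids = []
    for i, l in enumerate(loadings):
        idx = np.searchsorted(union, l.channels)
        mat[i, idx] = l.loadings
        ids.append(l.model_id or f"model{i}")
        if np.ptp(mat[i]) <= 0:
            raise ValueError(f"constant loading vector for {ids[-1]}")
    k = len(loadings)
    r = np.eye(k)
    mlogp = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            res = stats.pearsonr(mat[i], mat[j])
            r[i, j] = r[j, i] = res.statistic
            p = max(float(res.pvalue), np.finfo(float).tiny)
            mlogp[i, j] = mlogp[j, i] = -np.log10(p)
    return (pd.DataFrame(r, index=ids, columns=ids),
            pd.DataFrame(mlogp, index=ids, columns=ids))
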