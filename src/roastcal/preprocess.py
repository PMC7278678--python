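"""Fixed pretreatment chain for roast-gas mass spectra.

The order is part of the contract and is enforced by the pipeline:

1. bin ion flight times / fractional m/z to unit-mass channels 1-350,
2. average spectra to 5 s time resolution,
3. per-channel baseline correction (lower-percentile subtraction),
4. channel exclusion (m/z < 59, caffeine m/z 193-197, and channels below the
   detection threshold in more than 5% of the calibration spectra) — applied
   strictly *before* normalization,
5. L1 normalization of each spectrum over the retained channels,
6. mean centering with the calibration column means.

The fitted :class:`PreprocessState` is persisted and applied identically to
calibration, external-validation and streaming data.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from roastcal.containers import SpectraMatrix

__all__ = [
    "PreprocessState",
    "bin_to_unit_mz",
    "average_time",
    "baseline_correct",
    "detection_thresholds",
    "select_channels",
    "l1_normalize_then_center",
    "estimate_noise_deltax",
]

logger = logging.getLogger(__name__)

MZ_MIN = 59
MZ_MAX = 350
CAFFEINE_MZ = (193, 197)  # inclusive


@dataclass
class PreprocessState:
    """Persisted preprocessing state of a calibration.

    ``noise_deltax`` is the scalar instrumental noise estimate (descriptor
    units) pooled from the first 10 s of each calibration roast;
    ``norm_reference_total`` is the median L1 total of the calibration drop
    spectra, used to express raw early-window noise on the normalized scale.
    """

    retained_channels: np.ndarray
    column_means: np.ndarray
    noise_deltax: float = 0.0
    resolution_s: float = 5.0
    baseline_percentile: float = 10.0
    thresholds: np.ndarray | None = None
    norm_reference_total: float = 1.0

    def __post_init__(self) -> None:
        self.retained_channels = np.asarray(self.retained_channels, dtype=int)
        self.column_means = np.asarray(self.column_means, dtype=float)
        ch = self.retained_channels
        if ch.size and (ch.min() < MZ_MIN or ch.max() > MZ_MAX):
            raise ValueError(f"retained channels must lie in [{MZ_MIN}, {MZ_MAX}]")
        if np.any((ch >= CAFFEINE_MZ[0]) & (ch <= CAFFEINE_MZ[1])):
            raise ValueError("caffeine channels (m/z 193-197) must be excluded")
        if self.column_means.size != ch.size:
            raise ValueError("column_means length must match retained channels")
        if self.noise_deltax < 0:
            raise ValueError("noise estimate must be >= 0")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "retained_channels": self.retained_channels.tolist(),
            "column_means": self.column_means.tolist(),
            "noise_deltax": self.noise_deltax,
            "resolution_s": self.resolution_s,
            "baseline_percentile": self.baseline_percentile,
            "thresholds": None if self.thresholds is None else list(self.thresholds),
            "norm_reference_total": self.norm_reference_total,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "PreprocessState":
        d = json.loads(Path(path).read_text())
        thr = d.pop("thresholds")
        return cls(
            retained_channels=np.asarray(d.pop("retained_channels"), dtype=int),
            column_means=np.asarray(d.pop("column_means"), dtype=float),
            thresholds=None if thr is None else np.asarray(thr, dtype=float),
            **d,
        )


def bin_to_unit_mz(
    mz_values: np.ndarray, intensities: np.ndarray, mz_max: int = MZ_MAX
) -> np.ndarray:
    """Sum intensities into nearest-integer m/z bins 1..``mz_max``.

    Peaks binning above ``mz_max`` (or below 1) are dropped; the count of
    dropped peaks is logged.
    """
    mz_values = np.asarray(mz_values, dtype=float)
    intensities = np.asarray(intensities, dtype=float)
    if mz_values.size == 0:
        raise ValueError("empty input spectrum")
    if mz_values.size > 1 and np.any(np.diff(mz_values) < 0):
        raise ValueError("m/z axis must be monotone non-decreasing")
    bins = np.rint(mz_values).astype(int)
    keep = (bins >= 1) & (bins <= mz_max)
    n_dropped = int(np.count_nonzero(~keep))
    if n_dropped:
        logger.info("bin_to_unit_mz: dropped %d peaks outside 1-%d", n_dropped, mz_max)
    out = np.zeros(mz_max)
    np.add.at(out, bins[keep] - 1, intensities[keep])
    return out


def average_time(spectra: SpectraMatrix, window_s: float) -> SpectraMatrix:
    """Average spectra into non-overlapping time windows.

    Timestamps of the output are window centers.  A trailing partial window
    is averaged over the rows it has (logged).
    """
    t = spectra.time_s
    native = float(np.median(np.diff(t))) if t.size > 1 else window_s
    if window_s < native - 1e-9:
        raise ValueError(f"window {window_s}s below native resolution {native}s")
    per = max(1, int(round(window_s / native)))
    n_out = int(np.ceil(spectra.n_times / per))
    out = np.empty((n_out, spectra.n_channels))
    centers = np.empty(n_out)
    for i in range(n_out):
        rows = slice(i * per, min((i + 1) * per, spectra.n_times))
        out[i] = spectra.intensity[rows].mean(axis=0)
        centers[i] = i * window_s + window_s / 2.0
    if spectra.n_times % per:
        logger.info("average_time: trailing partial window averaged over "
                    "%d rows", spectra.n_times % per)
    return SpectraMatrix(centers, spectra.mz, out, spectra.wavelength_nm)


def baseline_correct(
    spectra: SpectraMatrix, percentile: float = 10.0
) -> SpectraMatrix:
    """Subtract a per-channel baseline and clip negatives to zero.

    The baseline of each channel is its lower ``percentile`` over the roast's
    time axis — deterministic and parameter-light, and exact (zero) for
    channels that are silent early in the roast.
    """
    base = np.percentile(spectra.intensity, percentile, axis=0)
    corrected = np.clip(spectra.intensity - base, 0.0, None)
    return SpectraMatrix(spectra.time_s.copy(), spectra.mz.copy(), corrected,
                         spectra.wavelength_nm)


def detection_thresholds(
    early_rows: np.ndarray, k_sigma: float = 3.0
) -> np.ndarray:
    """Per-channel detection thresholds from blank-region (first 10 s) rows.

    ``early_rows`` stacks the first-10-s spectra of every calibration roast
    (after baseline correction); the threshold is ``k_sigma`` times the
    per-channel standard deviation over that window.
    """
    early_rows = np.atleast_2d(np.asarray(early_rows, dtype=float))
    if early_rows.shape[0] < 2:
        raise ValueError("need at least 2 early-window rows")
    return k_sigma * early_rows.std(axis=0, ddof=1)


def select_channels(
    spectra_rows: np.ndarray,
    thresholds: np.ndarray,
    mz: np.ndarray | None = None,
    lod_rule_fraction: float = 0.05,
) -> np.ndarray:
    """Channels retained for calibration, ascending.

    Keeps m/z in [59, 350], drops the caffeine channels 193-197
    unconditionally (high variability between similar roasts), and drops any
    channel whose intensity falls below its detection threshold in more than
    ``lod_rule_fraction`` of the calibration spectra.
    """
    X = np.atleast_2d(np.asarray(spectra_rows, dtype=float))
    if mz is None:
        mz = np.arange(1, X.shape[1] + 1)
    mz = np.asarray(mz, dtype=int)
    below = (X < thresholds[None, :]).mean(axis=0)
    ok = (
        (mz >= MZ_MIN)
        & (mz <= MZ_MAX)
        & ~((mz >= CAFFEINE_MZ[0]) & (mz <= CAFFEINE_MZ[1]))
        & (below <= lod_rule_fraction)
    )
    retained = mz[ok]
    if retained.size == 0:
        raise ValueError("no channel survives exclusion: degenerate calibration")
    return np.sort(retained)


def l1_normalize_then_center(
    X: np.ndarray, state: PreprocessState, fit_mode: bool = False
) -> np.ndarray:
    """L1-normalize rows over the retained channels, then mean-center columns.

    ``X`` must already be restricted to ``state.retained_channels`` (in that
    order).  In fit mode the column means of the normalized calibration
    matrix are stored on ``state``; in apply mode the stored means are
    subtracted, so calibration, validation and streaming data share one
    centering.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != state.retained_channels.size:
        raise ValueError(
            f"expected {state.retained_channels.size} retained channels, "
            f"got {X.shape[1]}"
        )
    totals = np.abs(X).sum(axis=1)
    if np.any(totals <= 0):
        bad = np.flatnonzero(totals <= 0)
        raise ValueError(f"empty spectrum: zero total intensity in rows {bad.tolist()}")
    Xn = X / totals[:, None]
    if fit_mode:
        state.column_means = Xn.mean(axis=0)
    return Xn - state.column_means[None, :]


def estimate_noise_deltax(early_rows: np.ndarray) -> float:
    """Pooled scalar noise estimate from the first-10-s descriptor rows.

    Returns the root of the mean per-channel variance across the early
    window: a single scalar because the analytical sensitivity divides by a
    scalar noise.
    """
    early_rows = np.atleast_2d(np.asarray(early_rows, dtype=float))
    if early_rows.shape[0] < 2:
        raise ValueError("need at least 2 early-window rows to estimate noise")
    return float(np.sqrt(early_rows.var(axis=0, ddof=1).mean()))
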