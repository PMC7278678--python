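"""In-memory containers for roast-gas spectra and roast experiments."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SpectraMatrix", "RoastRecord"]


@dataclass
class SpectraMatrix:
    """One roast's time-binned intensity matrix.

    Rows are time bins (``time_s`` holds the bin centers in seconds), columns
    are integer m/z channels (``mz``). Intensities are in arbitrary detector
    units and must be non-negative for raw data; preprocessed matrices may
    contain negative (centered) values.
    """

    time_s: np.ndarray
    mz: np.ndarray
    intensity: np.ndarray
    wavelength_nm: float | None = None

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.mz = np.asarray(self.mz, dtype=int)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.shape != (self.time_s.size, self.mz.size):
            raise ValueError(
                f"intensity shape {self.intensity.shape} does not match "
                f"{self.time_s.size} time bins x {self.mz.size} channels"
            )
        if self.time_s.size > 1 and not np.all(np.diff(self.time_s) > 0):
            raise ValueError("time axis must be strictly increasing")

    @property
    def n_times(self) -> int:
        return self.time_s.size

    @property
    def n_channels(self) -> int:
        return self.mz.size

    def channel(self, mz: int) -> np.ndarray:
        """Time trace of a single integer m/z channel."""
        idx = np.flatnonzero(self.mz == mz)
        if idx.size == 0:
            raise KeyError(f"m/z {mz} not present")
        return self.intensity[:, idx[0]]

    def copy(self) -> "SpectraMatrix":
        return SpectraMatrix(
            self.time_s.copy(), self.mz.copy(), self.intensity.copy(),
            self.wavelength_nm,
        )


@dataclass
class RoastRecord:
    """One roast experiment: spectra plus per-roast reference measurements.

    ``colorette`` is the roast-degree reflectance value (dimensionless,
    calibrated 0-200, lower = darker); ``fc_value`` is the brew antioxidant
    capacity from the Folin-Ciocalteu assay in gallic-acid-equivalent mg/L.
    ``truth`` carries the latent roast-progress trajectory and noise-free
    property curves; it is populated by the simulator only and is never
    consulted by the calibration code.
    """

    spectra: SpectraMatrix
    colorette: float
    fc_value: float
    drop_time_s: float
    wavelength_nm: float
    roast_id: str = ""
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.colorette <= 200.0:
            raise ValueError(f"Colorette {self.colorette} outside the 0-200 scale")
        if self.fc_value < 0:
            raise ValueError("FC value must be non-negative")
        tmax = float(self.spectra.time_s[-1]) + 2.5 if self.spectra.n_times else 0.0
        if self.drop_time_s <= 0 or self.drop_time_s > tmax + 5.0:
            raise ValueError("drop time outside the simulated duration")
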