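"""File formats and pipeline configuration.

Spectra travel either as a wide CSV (rows = time bins, columns = integer
m/z, first column ``time_s``) or as an HDF5 container with datasets
``/mz``, ``/time_s``, ``/intensity`` and attributes ``wavelength_nm`` and
``seed``.  Campaign metadata is a CSV table; the pipeline configuration is
YAML.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from roastcal.containers import RoastRecord, SpectraMatrix
from roastcal.synthetic import CampaignConfig

__all__ = [
    "write_spectra_csv",
    "read_spectra_csv",
    "write_spectra_hdf5",
    "read_spectra_hdf5",
    "read_spectra",
    "write_campaign",
    "read_campaign",
    "PipelineConfig",
    "config_hash",
]


def write_spectra_csv(spectra: SpectraMatrix, path: str | Path) -> None:
    path = Path(path)
    df = pd.DataFrame(spectra.intensity, columns=spectra.mz.astype(str))
    df.insert(0, "time_s", spectra.time_s)
    df.to_csv(path, index=False, float_format="%.9g")


def read_spectra_csv(path: str | Path) -> SpectraMatrix:
    path = Path(path)
    if path.stat().st_size == 0:
        raise ValueError(f"{path}: empty file")
    with open(path) as fh:
        header = fh.readline().strip().split(",")
    if not header or header[0] != "time_s":
        raise ValueError(f"{path}: first column must be time_s (line 1)")
    try:
        mz = np.array([int(c) for c in header[1:]])
    except ValueError as exc:
        raise ValueError(f"{path}: non-integer m/z column header: {exc}") from exc
    if np.unique(mz).size != mz.size:
        counts = np.bincount(mz)
        dup = np.flatnonzero(counts > 1)
        raise ValueError(f"{path}: duplicated m/z columns {dup.tolist()}")
    df = pd.read_csv(path)
    cols = list(df.columns[1:])
    t = df["time_s"].to_numpy(dtype=float)
    if t.size > 1 and np.any(np.diff(t) <= 0):
        bad = int(np.flatnonzero(np.diff(t) <= 0)[0]) + 2  # header is line 1
        raise ValueError(f"{path}: non-monotone time axis near line {bad + 1}")
    return SpectraMatrix(t, mz, df[cols].to_numpy(dtype=float))


def write_spectra_hdf5(
    spectra: SpectraMatrix, path: str | Path, seed: int | None = None
) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("mz", data=spectra.mz)
        f.create_dataset("time_s", data=spectra.time_s)
        f.create_dataset("intensity", data=spectra.intensity)
        if spectra.wavelength_nm is not None:
            f.attrs["wavelength_nm"] = spectra.wavelength_nm
        if seed is not None:
            f.attrs["seed"] = seed


def read_spectra_hdf5(path: str | Path) -> SpectraMatrix:
    with h5py.File(path, "r") as f:
        return SpectraMatrix(
            f["time_s"][:], f["mz"][:], f["intensity"][:],
            float(f.attrs["wavelength_nm"]) if "wavelength_nm" in f.attrs else None,
        )


def read_spectra(path: str | Path) -> SpectraMatrix:
    """Dispatch on extension: .csv or .h5/.hdf5."""
    path = Path(path)
    if path.suffix == ".csv":
        return read_spectra_csv(path)
    if path.suffix in (".h5", ".hdf5"):
        return read_spectra_hdf5(path)
    raise ValueError(f"unrecognized spectra extension {path.suffix!r}")


def write_campaign(
    records: list[RoastRecord], outdir: str | Path, fmt: str = "csv"
) -> None:
    """Write a campaign: one spectra file per roast plus a metadata table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, rec in enumerate(records):
        rid = rec.roast_id or f"roast{i:03d}"
        fname = f"{rid}.{'csv' if fmt == 'csv' else 'h5'}"
        sm = rec.spectra
        if fmt == "csv":
            write_spectra_csv(sm, outdir / fname)
        else:
            write_spectra_hdf5(sm, outdir / fname)
        rows.append({
            "roast_id": rid,
            "drop_time_s": rec.drop_time_s,
            "colorette": rec.colorette,
            "fc_mg_per_L": rec.fc_value,
            "wavelength_nm": rec.wavelength_nm,
            "spectra_file": fname,
        })
    pd.DataFrame(rows).to_csv(outdir / "metadata.csv", index=False,
                              float_format="%.9g")


def read_campaign(indir: str | Path) -> list[RoastRecord]:
    indir = Path(indir)
    meta = pd.read_csv(indir / "metadata.csv")
    records = []
    for _, row in meta.iterrows():
        sm = read_spectra(indir / row["spectra_file"])
        if sm.wavelength_nm is None:
            sm.wavelength_nm = float(row["wavelength_nm"])
        records.append(RoastRecord(
            spectra=sm,
            colorette=float(row["colorette"]),
            fc_value=float(row["fc_mg_per_L"]),
            drop_time_s=float(row["drop_time_s"]),
            wavelength_nm=float(row["wavelength_nm"]),
            roast_id=str(row["roast_id"]),
        ))
    return records


@dataclass
class PipelineConfig:
    """Single structured configuration driving the whole pipeline.

    All seeds are explicit; the config serializes round-trip stably to YAML
    and its hash goes into the run manifest.
    """

    seed: int
    n_roasts: int = 84
    wavelength_nm: float = 248.0
    drop_time_range: tuple[float, float] = (420.0, 840.0)
    additive_noise_sd: float = 0.15
    multiplicative_sigma: float = 0.05
    colorette_noise_sd: float = 2.0
    fc_noise_sd: float = 40.0
    campaign_dir: str | None = None
    spectra_format: str = "csv"
    resolution_s: float = 5.0
    baseline_percentile: float = 10.0
    lod_rule_fraction: float = 0.05
    max_components: int = 20
    cv_repeats: int = 1000
    frac_train: float = 0.8
    cars_enabled: bool = True
    cars_runs: int = 50
    cars_repetitions: int = 100
    alpha: float = 0.05
    split_seed: int = field(default=None)  # type: ignore[assignment]
    analysis_seed: int = field(default=None)  # type: ignore[assignment]
    online_seed: int = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("config requires an explicit seed")
        rng = np.random.default_rng(self.seed)
        children = rng.integers(0, 2**31, size=3)
        if self.split_seed is None:
            self.split_seed = int(children[0])
        if self.analysis_seed is None:
            self.analysis_seed = int(children[1])
        if self.online_seed is None:
            self.online_seed = int(children[2])
        self.drop_time_range = tuple(float(v) for v in self.drop_time_range)

    def campaign_config(self) -> CampaignConfig:
        return CampaignConfig(
            seed=self.seed, n_roasts=self.n_roasts,
            drop_time_range=self.drop_time_range,
            wavelength_nm=self.wavelength_nm, resolution_s=self.resolution_s,
            additive_noise_sd=self.additive_noise_sd,
            multiplicative_sigma=self.multiplicative_sigma,
            colorette_noise_sd=self.colorette_noise_sd,
            fc_noise_sd=self.fc_noise_sd,
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["drop_time_range"] = list(self.drop_time_range)
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "drop_time_range" in d:
            d["drop_time_range"] = tuple(d["drop_time_range"])
        return cls(**d)


def config_hash(config: PipelineConfig) -> str:
    canon = json.dumps(config.to_dict(), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()
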