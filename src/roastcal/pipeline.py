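"""End-to-end calibration pipeline and the persisted calibration bundle.

Chains the stages in their fixed order: time averaging, baseline
correction, channel exclusion, L1 normalization + centering (fitted on the
calibration roasts only), Monte Carlo CV for the component count, CARS
variable selection, the final PLS refit, figures of merit on the external
set, target-projection loadings and an online-prediction demonstration.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from roastcal.containers import RoastRecord, SpectraMatrix
from roastcal.fom import FiguresOfMerit, compute_figures_of_merit, rmse
from roastcal.online import degrees_of_freedom, predict_stream
from roastcal.pls import PLSModel, fit_pls, predict
from roastcal.preprocess import (
    PreprocessState,
    average_time,
    baseline_correct,
    detection_thresholds,
    estimate_noise_deltax,
    l1_normalize_then_center,
    select_channels,
)
from roastcal.selection import (
    CARSResult,
    CVResult,
    cars_select,
    monte_carlo_cv,
    select_n_components,
    split_calibration_external,
)
from roastcal.synthetic import CampaignConfig, simulate_campaign, simulate_roast
from roastcal.targetproj import tp_correlation_matrix, tp_loadings

__all__ = [
    "CalibrationBundle",
    "fit_preprocessor",
    "apply_preprocessor",
    "calibrate_records",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

EARLY_WINDOW_S = 10.0  # blank region used for noise and detection thresholds


def _corrected(record: RoastRecord, resolution_s: float,
               percentile: float) -> SpectraMatrix:
    sm = record.spectra
    native = float(np.median(np.diff(sm.time_s))) if sm.n_times > 1 else resolution_s
    if native < resolution_s - 1e-9:
        sm = average_time(sm, resolution_s)
    return baseline_correct(sm, percentile)


def _drop_and_early_rows(
    records: list[RoastRecord], resolution_s: float, percentile: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Baseline-corrected drop spectra and first-10-s rows of each roast."""
    drops, early = [], []
    mz = records[0].spectra.mz
    for rec in records:
        if not np.array_equal(rec.spectra.mz, mz):
            raise ValueError("records have inconsistent m/z axes")
        bc = _corrected(rec, resolution_s, percentile)
        drops.append(bc.intensity[-1])
        early.append(bc.intensity[bc.time_s < EARLY_WINDOW_S])
    return np.vstack(drops), np.vstack(early), mz


def fit_preprocessor(
    records: list[RoastRecord],
    resolution_s: float = 5.0,
    baseline_percentile: float = 10.0,
    lod_rule_fraction: float = 0.05,
    k_sigma: float = 3.0,
) -> tuple[np.ndarray, PreprocessState]:
    """Fit the preprocessing state on calibration roasts; return descriptors.

    One drop spectrum per roast enters calibration.  Detection thresholds
    come from the pooled first-10-s blank region; the scalar noise estimate
    δx is the pooled early-window noise expressed on the descriptor scale
    (divided by the median drop-spectrum total over the retained channels).
    """
    drops, early, mz = _drop_and_early_rows(records, resolution_s,
                                            baseline_percentile)
    thresholds = detection_thresholds(early, k_sigma=k_sigma)
    retained = select_channels(drops, thresholds, mz=mz,
                               lod_rule_fraction=lod_rule_fraction)
    cols = np.searchsorted(mz, retained)
    Xr = drops[:, cols]
    ref_total = float(np.median(np.abs(Xr).sum(axis=1)))
    state = PreprocessState(
        retained_channels=retained,
        column_means=np.zeros(retained.size),
        resolution_s=resolution_s,
        baseline_percentile=baseline_percentile,
        thresholds=thresholds[cols],
        norm_reference_total=ref_total,
    )
    X = l1_normalize_then_center(Xr, state, fit_mode=True)
    state.noise_deltax = estimate_noise_deltax(early[:, cols] / ref_total)
    return X, state


def apply_preprocessor(
    records: list[RoastRecord], state: PreprocessState
) -> np.ndarray:
    """Apply a fitted preprocessing state to new roasts (drop spectra)."""
    drops, _, mz = _drop_and_early_rows(records, state.resolution_s,
                                        state.baseline_percentile)
    missing = np.setdiff1d(state.retained_channels, mz)
    if missing.size:
        raise ValueError(f"records lack retained channels {missing.tolist()}")
    cols = np.searchsorted(mz, state.retained_channels)
    return l1_normalize_then_center(drops[:, cols], state, fit_mode=False)


@dataclass
class CalibrationBundle:
    """Everything needed to predict new spectra and quantify uncertainty.

    ``mask`` selects the CARS-retained variables among the preprocessing
    state's retained channels.  ``sde`` and ``df`` parameterize the
    error-in-variable prediction interval; ``rmse_p`` (external validation,
    falls back to RMSE_CV until an external set has been evaluated) draws the
    constant error band.
    """

    state: PreprocessState
    model: PLSModel
    mask: np.ndarray
    property_name: str
    wavelength_nm: float
    n_cal: int
    y_cal_min: float
    y_cal_max: float
    rmse_cv: float
    r2_cv: float
    sde: float
    df: float
    rmse_p: float
    seed: int
    cv: CVResult | None = None
    cars: CARSResult | None = None

    @property
    def selected_channels(self) -> np.ndarray:
        return self.state.retained_channels[self.mask]

    def predict_records(self, records: list[RoastRecord]) -> np.ndarray:
        X = apply_preprocessor(records, self.state)
        return predict(self.model, X[:, self.mask])

    def save(self, path: str | Path) -> None:
        m = self.model
        payload = {
            "property_name": self.property_name,
            "wavelength_nm": self.wavelength_nm,
            "n_cal": self.n_cal,
            "y_cal_min": self.y_cal_min,
            "y_cal_max": self.y_cal_max,
            "rmse_cv": self.rmse_cv,
            "r2_cv": self.r2_cv,
            "sde": self.sde,
            "df": self.df,
            "rmse_p": self.rmse_p,
            "seed": self.seed,
            "mask": self.mask.astype(int).tolist(),
            "state": {
                "retained_channels": self.state.retained_channels.tolist(),
                "column_means": self.state.column_means.tolist(),
                "noise_deltax": self.state.noise_deltax,
                "resolution_s": self.state.resolution_s,
                "baseline_percentile": self.state.baseline_percentile,
                "thresholds": None if self.state.thresholds is None
                else list(map(float, self.state.thresholds)),
                "norm_reference_total": self.state.norm_reference_total,
            },
            "model": {
                "weights": m.weights.tolist(),
                "x_loadings": m.x_loadings.tolist(),
                "y_loadings": m.y_loadings.tolist(),
                "scores": m.scores.tolist(),
                "b": m.b.tolist(),
                "coef_path": m.coef_path.tolist(),
                "n_components": m.n_components,
                "y_mean": m.y_mean,
                "x_mean": m.x_mean.tolist(),
            },
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "CalibrationBundle":
        d = json.loads(Path(path).read_text())
        sd = d.pop("state")
        thr = sd.pop("thresholds")
        state = PreprocessState(
            retained_channels=np.asarray(sd.pop("retained_channels"), dtype=int),
            column_means=np.asarray(sd.pop("column_means"), dtype=float),
            thresholds=None if thr is None else np.asarray(thr, dtype=float),
            **sd,
        )
        md = d.pop("model")
        model = PLSModel(
            weights=np.asarray(md["weights"], dtype=float),
            x_loadings=np.asarray(md["x_loadings"], dtype=float),
            y_loadings=np.asarray(md["y_loadings"], dtype=float),
            scores=np.asarray(md["scores"], dtype=float),
            b=np.asarray(md["b"], dtype=float),
            coef_path=np.asarray(md["coef_path"], dtype=float),
            n_components=int(md["n_components"]),
            y_mean=float(md["y_mean"]),
            x_mean=np.asarray(md["x_mean"], dtype=float),
        )
        mask = np.asarray(d.pop("mask"), dtype=bool)
        return cls(state=state, model=model, mask=mask, **d)


def calibrate_records(
    records: list[RoastRecord],
    property_name: str = "colorette",
    seed: int = 0,
    max_components: int = 20,
    cv_repeats: int = 1000,
    frac_train: float = 0.8,
    do_cars: bool = True,
    cars_runs: int = 50,
    cars_repetitions: int = 100,
    resolution_s: float = 5.0,
    baseline_percentile: float = 10.0,
    lod_rule_fraction: float = 0.05,
) -> CalibrationBundle:
    """Calibrate one property on a set of roasts.

    Runs the full model-development chain on ``records`` (assumed to be the
    calibration set): preprocessing fit, Monte Carlo CV over component
    counts, CARS variable selection (its internal component cap is the
    pre-CARS selection, so refinement can only simplify the model), a final
    refit on the surviving variables, and the uncertainty parameters (sde
    and pseudo degrees of freedom) for prediction intervals.
    """
    rng = np.random.default_rng(seed)
    X, state = fit_preprocessor(
        records, resolution_s=resolution_s,
        baseline_percentile=baseline_percentile,
        lod_rule_fraction=lod_rule_fraction,
    )
    y = np.array([getattr(r, property_name) for r in records], dtype=float)
    n, p = X.shape

    cv_full = monte_carlo_cv(X, y, max_components=max_components,
                             frac_train=frac_train, n_repeats=cv_repeats,
                             seed=int(rng.integers(0, 2**31)))
    k_full = select_n_components(cv_full)
    logger.info("calibrate[%s]: pre-CARS selection %d components on %d channels",
                property_name, k_full, p)

    cars = None
    if do_cars and p >= 2:
        cars = cars_select(
            X, y, n_cars_runs=cars_runs, n_repetitions=cars_repetitions,
            max_components=k_full, seed=int(rng.integers(0, 2**31)),
        )
        mask = cars.mask
        k = cars.n_components
    else:
        mask = np.ones(p, dtype=bool)
        k = k_full

    cv_final = monte_carlo_cv(X[:, mask], y, max_components=max(k, 1),
                              frac_train=frac_train, n_repeats=cv_repeats,
                              seed=int(rng.integers(0, 2**31)))
    model = fit_pls(X[:, mask], y, k, strict=False)
    rmse_fit = rmse(predict(model, X[:, mask]), y)
    rmse_cv_k = float(cv_final.rmse_cv[k - 1])
    r2_cv_k = float(cv_final.r2_cv[k - 1])
    df = degrees_of_freedom(n, rmse_fit=rmse_fit, rmse_cv=rmse_cv_k,
                            method="pseudo")
    sde = float(rmse_fit * np.sqrt(n / df))
    return CalibrationBundle(
        state=state, model=model, mask=mask, property_name=property_name,
        wavelength_nm=records[0].wavelength_nm, n_cal=n,
        y_cal_min=float(y.min()), y_cal_max=float(y.max()),
        rmse_cv=rmse_cv_k, r2_cv=r2_cv_k, sde=sde, df=df,
        rmse_p=rmse_cv_k, seed=seed, cv=cv_full, cars=cars,
    )


def evaluate_external(
    bundle: CalibrationBundle,
    records: list[RoastRecord],
    var_ycal_err: float = 0.0,
    y_cal: np.ndarray | None = None,
    X_cal: np.ndarray | None = None,
) -> FiguresOfMerit:
    """Figures of merit of a bundle on an external validation set.

    Also stores the external RMSE_P on the bundle (used for the constant
    error band in online prediction).
    """
    if y_cal is None or X_cal is None:
        raise ValueError("pass the calibration descriptors and responses")
    y_ext = np.array([getattr(r, bundle.property_name) for r in records])
    y_hat_ext = bundle.predict_records(records)
    Xm = X_cal[:, bundle.mask]
    fom = compute_figures_of_merit(
        y_cal=y_cal, y_hat_cal=predict(bundle.model, Xm),
        y_ext=y_ext, y_hat_ext=y_hat_ext,
        b=bundle.model.b, X_cal=Xm, delta_x=bundle.state.noise_deltax,
        rmse_cv=bundle.rmse_cv, r2_cv=bundle.r2_cv,
        var_ycal_err=var_ycal_err,
    )
    bundle.rmse_p = fom.rmse_p
    return fom


def run_pipeline(config: "PipelineConfig", outdir: str | Path) -> dict:
    """Run the whole pipeline from a config; write artifacts and a manifest.

    Stages: simulate (or load) campaign -> 4:1 split -> preprocess ->
    Monte Carlo CV -> CARS -> refit -> figures of merit -> TP loadings and
    their correlation matrix -> online prediction demo on a fresh roast.
    Rerunning with the same config reproduces every artifact.
    """
    from roastcal.io import (  # local import to avoid a cycle
        PipelineConfig, config_hash, read_campaign, write_campaign,
        write_spectra_csv,
    )
    import pandas as pd

    if not isinstance(config, PipelineConfig):
        raise TypeError("run_pipeline expects a PipelineConfig")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if config.campaign_dir:
        records = read_campaign(config.campaign_dir)
    else:
        records = simulate_campaign(config.campaign_config())
        write_campaign(records, outdir / "campaign", fmt=config.spectra_format)

    cal, ext = split_calibration_external(records, seed=config.split_seed)
    artifacts: dict = {"records": records, "calibration": cal, "external": ext}
    fom_rows = []
    tps = []
    for prop in ("colorette", "fc_value"):
        bundle = calibrate_records(
            cal, property_name=prop, seed=config.analysis_seed,
            max_components=config.max_components, cv_repeats=config.cv_repeats,
            frac_train=config.frac_train, do_cars=config.cars_enabled,
            cars_runs=config.cars_runs,
            cars_repetitions=config.cars_repetitions,
            resolution_s=config.resolution_s,
            baseline_percentile=config.baseline_percentile,
            lod_rule_fraction=config.lod_rule_fraction,
        )
        X_cal = apply_preprocessor(cal, bundle.state)
        y_cal = np.array([getattr(r, prop) for r in cal])
        fom = evaluate_external(bundle, ext, var_ycal_err=0.0,
                                y_cal=y_cal, X_cal=X_cal)
        tp = tp_loadings(bundle.model, X_cal[:, bundle.mask],
                         channels=bundle.selected_channels,
                         model_id=f"{prop}_{int(bundle.wavelength_nm)}nm")
        tps.append(tp)
        bundle.save(outdir / f"bundle_{prop}.json")
        from roastcal.fom import residual_diagnostics

        y_hat_cal = predict(bundle.model, X_cal[:, bundle.mask])
        diag = residual_diagnostics(y_cal - y_hat_cal, y_hat_cal,
                                    n_permutations=2000,
                                    seed=config.analysis_seed)
        row = {"property": prop, **fom.to_dict(),
               "n_components": bundle.model.n_components,
               "n_variables": int(bundle.mask.sum()),
               "shapiro_p": diag["shapiro_p"],
               "perm_p_deg1": diag["perm_p_deg1"],
               "perm_p_deg2": diag["perm_p_deg2"]}
        fom_rows.append(row)
        tp.to_frame().to_csv(outdir / f"tp_loadings_{prop}.csv", index=False)
        cvd = bundle.cv
        pd.DataFrame({
            "components": cvd.components, "rmse_fit": cvd.rmse_fit,
            "rmse_cv": cvd.rmse_cv, "r2_fit": cvd.r2_fit, "r2_cv": cvd.r2_cv,
        }).to_csv(outdir / f"cv_curve_{prop}.csv", index=False)
        artifacts[f"bundle_{prop}"] = bundle
        artifacts[f"fom_{prop}"] = fom

    pd.DataFrame(fom_rows).to_csv(outdir / "figures_of_merit.csv", index=False)
    r_df, mlogp_df = tp_correlation_matrix(tps)
    r_df.to_csv(outdir / "tp_correlation_r.csv")
    mlogp_df.to_csv(outdir / "tp_correlation_neglog10p.csv")
    artifacts["tp_correlation"] = (r_df, mlogp_df)

    # online demo: a fresh full-length roast not in the campaign
    demo = simulate_roast(config.campaign_config(),
                          config.campaign_config().drop_time_range[1],
                          seed=config.online_seed, roast_id="online-demo")
    write_spectra_csv(demo.spectra, outdir / "online_demo_spectra.csv")
    for prop in ("colorette", "fc_value"):
        series = predict_stream(artifacts[f"bundle_{prop}"], demo.spectra,
                                alpha=config.alpha)
        series.to_csv(outdir / f"online_{prop}.csv", index=False)
        artifacts[f"online_{prop}"] = series

    manifest = {
        "config_hash": config_hash(config),
        "config": config.to_dict(),
        "package_version": __import__("roastcal").__version__,
        "n_records": len(records),
        "n_calibration": len(cal),
        "n_external": len(ext),
        "artifacts": sorted(p.name for p in outdir.iterdir() if p.is_file()),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                     sort_keys=True))
    artifacts["manifest"] = manifest
    return artifacts
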