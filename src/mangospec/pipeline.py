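"""Experiment orchestration: simulate/load, preprocess, select, fit, report.

``run_experiment`` executes the full analysis flow on one config: obtain
quality records and ROI spectra (synthetic by default), compute per-group
attribute statistics, fit a CARS-PLS regression per attribute x drop height
x day with a seeded calibration/validation split, label fruits by ripening
index, fit a Fisher discriminant classifier on CARS-selected bands, and
write the report bundle (stats, regression and confusion tables, CARS
diagnostics, run manifest) as CSV/JSON.

Every stage's randomness is derived from the single config seed through a
SeedSequence spawn, so reruns of the same config reproduce all tables
byte-for-byte.  No stage sees validation or test rows while fitting:
the MSC reference, CARS subsets and PLS components all come from the
calibration side alone.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cars import CarsConfig, cars_run, report_cars_diagnostics
from .classify import classify, confusion, fit_lda, split_train_test
from .pls import (
    fit_pls,
    loo_cv,
    predict,
    regression_metrics,
    split_calibration_validation,
)
from .preprocess import SpectraMatrix, apply_named, msc_fit
from .quality import DamageThresholds, damage_class, records_to_frame
from .simulate import SimConfig, generate_dataset

__all__ = ["ExperimentConfig", "run_experiment", "default_config", "load_config"]

ATTRIBUTES = ("firmness", "tss", "ta", "chroma")


@dataclass
class ExperimentConfig:
    seed: int = 0
    output_dir: str = "runs/default"
    preprocessing: str = "snv"          # snv | sg | msc | none
    sg_window: int = 11
    sg_polyorder: int = 2
    calibration_ratio: float = 3 / 5    # per-group regression split
    train_ratio: float = 3 / 4          # classifier split
    cars_enabled: bool = True
    cars_runs: int = 50
    cars_mc_ratio: float = 0.8
    cars_components: int = 5
    pls_max_components: int = 10
    thresholds: DamageThresholds = field(default_factory=DamageThresholds)
    mode: str = "per_group"             # per_group | pooled regression
    sim: SimConfig = field(default_factory=SimConfig)
    quality_csv: str | None = None      # load measured data instead of simulating
    spectra_csv: str | None = None


def default_config(seed: int = 0, output_dir: str = "runs/default") -> ExperimentConfig:
    return ExperimentConfig(seed=seed, output_dir=output_dir,
                            sim=SimConfig(seed=seed))


def load_config(path: str | Path) -> ExperimentConfig:
    """Build an ExperimentConfig from a YAML file (missing keys -> defaults)."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    seed = int(raw.get("seed", 0))
    sim_kwargs = raw.get("simulate", {}) or {}
    for tup_key in ("heights", "days"):
        if tup_key in sim_kwargs:
            sim_kwargs[tup_key] = tuple(sim_kwargs[tup_key])
    thr = raw.get("rpi_thresholds", {}) or {}
    cars = raw.get("cars", {}) or {}
    sg = raw.get("sg", {}) or {}
    split = raw.get("split", {}) or {}
    data = raw.get("data", {}) or {}
    return ExperimentConfig(
        seed=seed,
        output_dir=str(raw.get("output_dir", "runs/default")),
        preprocessing=str(raw.get("preprocessing", "snv")),
        sg_window=int(sg.get("window", 11)),
        sg_polyorder=int(sg.get("polyorder", 2)),
        calibration_ratio=float(split.get("calibration_ratio", 3 / 5)),
        train_ratio=float(split.get("train_ratio", 3 / 4)),
        cars_enabled=bool(cars.get("enabled", True)),
        cars_runs=int(cars.get("n_runs", 50)),
        cars_mc_ratio=float(cars.get("mc_sample_ratio", 0.8)),
        cars_components=int(cars.get("pls_components", 5)),
        pls_max_components=int(raw.get("pls", {}).get("max_components", 10)),
        thresholds=DamageThresholds(
            slight_min=float(thr.get("slight_min", 7.0)),
            serious_max=float(thr.get("serious_max", 5.0)),
        ),
        mode=str(raw.get("mode", "per_group")),
        sim=SimConfig(seed=seed, **sim_kwargs),
        quality_csv=data.get("quality_csv"),
        spectra_csv=data.get("spectra_csv"),
    )


def _preprocess_split(cfg, spectra: SpectraMatrix, cal_rows, other_rows):
    """Apply the configured transform without leaking across the split.

    SNV and S-G act per spectrum; the MSC reference is frozen on the
    calibration rows and reused for the held-out rows.
    """
    ref = None
    if cfg.preprocessing == "msc":
        cal_matrix = SpectraMatrix(
            [spectra.sample_ids[i] for i in cal_rows], spectra.grid,
            spectra.values[cal_rows], spectra.provenance,
        )
        ref = msc_fit(cal_matrix)
    out = apply_named(spectra, cfg.preprocessing, reference=ref,
                      window=cfg.sg_window, polyorder=cfg.sg_polyorder)
    return out


def _fit_group_model(cfg, X, y, grid, rng):
    """CARS (optional) + LOO-sized PLS on calibration data; returns details."""
    n = X.shape[0]
    if cfg.cars_enabled:
        cars_cfg = CarsConfig(
            n_runs=cfg.cars_runs, mc_sample_ratio=cfg.cars_mc_ratio,
            pls_components=cfg.cars_components,
            seed=int(rng.integers(2**31 - 1)),
        )
        sel = cars_run(X, y, cars_cfg, grid=grid).selected
    else:
        sel = np.arange(X.shape[1])
    a_max = min(cfg.pls_max_components, n - 2, sel.size)
    cv = loo_cv(X[:, sel], y, max_components=a_max)
    model = fit_pls(X[:, sel], y, cv.n_components)
    return model, sel, cv


def run_experiment(cfg: ExperimentConfig) -> dict:
    """Run the full pipeline; returns paths and in-memory results."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    ss = np.random.SeedSequence(cfg.seed)
    rng_split, rng_cars, rng_cls = (
        np.random.default_rng(s) for s in ss.spawn(3)
    )

    # ------------------------------------------------------------------ data
    if cfg.quality_csv and cfg.spectra_csv:
        quality = pd.read_csv(cfg.quality_csv)
        spectra = SpectraMatrix.from_csv(cfg.spectra_csv)
        truth = None
    else:
        dataset = generate_dataset(replace(cfg.sim, seed=cfg.seed))
        quality = records_to_frame(dataset.records)
        spectra = dataset.spectra
        truth = dataset.ground_truth
    quality = quality.reset_index(drop=True)

    # --------------------------------------------- quality statistics table
    damaged = quality[quality.drop_height > 0]
    stats = (
        damaged.melt(
            id_vars=["drop_height", "day"],
            value_vars=[*ATTRIBUTES, "rpi"],
            var_name="attribute",
        )
        .groupby(["attribute", "drop_height", "day"])["value"]
        .agg(["mean", "std"])
        .round(2)
        .reset_index()
    )
    stats_path = out / "quality_stats.csv"
    stats.to_csv(stats_path, index=False)

    # -------------------------------------------------- per-group regression
    reg_rows = []
    groups = (
        [(h, d) for h in sorted(damaged.drop_height.unique())
         for d in sorted(damaged.day.unique())]
        if cfg.mode == "per_group" else [(None, None)]
    )
    for height, day in groups:
        if height is None:
            grp_idx = damaged.index.to_numpy()
        else:
            grp_idx = damaged.index[
                (damaged.drop_height == height) & (damaged.day == day)
            ].to_numpy()
        cal_loc, val_loc = split_calibration_validation(
            grp_idx.size, ratio=cfg.calibration_ratio, seed=rng_split
        )
        cal_idx, val_idx = grp_idx[cal_loc], grp_idx[val_loc]
        pre = _preprocess_split(cfg, spectra, cal_idx, val_idx)
        Xc, Xv = pre.values[cal_idx], pre.values[val_idx]
        for attr in ATTRIBUTES:
            y = quality[attr].to_numpy(float)
            model, sel, cv = _fit_group_model(
                cfg, Xc, y[cal_idx], pre.grid, rng_cars
            )
            m = regression_metrics(y[val_idx], predict(model, Xv[:, sel]))
            reg_rows.append(
                {
                    "attribute": attr,
                    "drop_height": height if height is not None else "pooled",
                    "day": day if day is not None else "all",
                    "n_cal": cal_idx.size,
                    "n_val": val_idx.size,
                    "n_bands": int(sel.size),
                    "n_components": model.n_components,
                    "r2_p": round(m.r2, 3),
                    "rmsep": round(m.rmse, 3),
                }
            )
    reg = pd.DataFrame(reg_rows)
    reg_path = out / "regression_results.csv"
    reg.to_csv(reg_path, index=False)

    # -------------------------------------------------------- classification
    dmg = quality[quality.drop_height > 0].reset_index(drop=True)
    labels = np.array(
        [damage_class(r, cfg.thresholds) for r in dmg.rpi.to_numpy(float)]
    )
    dmg_spectra = SpectraMatrix(
        list(dmg.fruit_id.astype(str)), spectra.grid,
        spectra.values[quality.drop_height.to_numpy() > 0],
        spectra.provenance,
    )
    tr, te = split_train_test(labels, ratio=cfg.train_ratio, seed=rng_cls)
    pre_cls = _preprocess_split(cfg, dmg_spectra, tr, te)
    if cfg.cars_enabled:
        # band selection against RPI on the training side only
        cars_cfg = CarsConfig(
            n_runs=cfg.cars_runs, mc_sample_ratio=cfg.cars_mc_ratio,
            pls_components=cfg.cars_components,
            seed=int(rng_cls.integers(2**31 - 1)),
        )
        cars_res = cars_run(
            pre_cls.values[tr], dmg.rpi.to_numpy(float)[tr], cars_cfg,
            grid=pre_cls.grid,
        )
        sel_cls = cars_res.selected
        report_cars_diagnostics(cars_res).to_csv(
            out / "cars_diagnostics.csv", index=False
        )
        pd.DataFrame(
            {"band_index": sel_cls, "wavelength_nm": cars_res.wavelengths_nm}
        ).to_csv(out / "cars_selected_wavelengths.csv", index=False)
    else:
        sel_cls = np.arange(pre_cls.grid.count)
    da = fit_lda(pre_cls.values[np.ix_(tr, sel_cls)], labels[tr])
    conf_train = confusion(
        labels[tr], classify(da, pre_cls.values[np.ix_(tr, sel_cls)]),
        classes=da.classes, split="training",
    )
    conf_test = confusion(
        labels[te], classify(da, pre_cls.values[np.ix_(te, sel_cls)]),
        classes=da.classes, split="testing",
    )
    conf_train.to_frame().to_csv(out / "confusion_training.csv")
    conf_test.to_frame().to_csv(out / "confusion_testing.csv")

    # --------------------------------------------------------------- outputs
    quality_path = out / "quality_records.csv"
    quality.to_csv(quality_path, index=False)
    spectra.to_csv(out / "spectra.csv")

    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "preprocessing": cfg.preprocessing,
        "mode": cfg.mode,
        "cars": {
            "enabled": cfg.cars_enabled,
            "n_runs": cfg.cars_runs,
            "mc_sample_ratio": cfg.cars_mc_ratio,
        },
        "classifier_pooling": "all damaged fruits across heights and days",
        "thresholds": asdict(cfg.thresholds),
        "n_records": int(len(quality)),
        "elapsed_s": round(time.time() - t0, 2),
        "outputs": {
            p.name: hashlib.sha256(p.read_bytes()).hexdigest()
            for p in sorted(out.glob("*.csv"))
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)

    return {
        "output_dir": out,
        "stats": stats,
        "regression": reg,
        "confusion_training": conf_train,
        "confusion_testing": conf_test,
        "ground_truth": truth,
        "manifest": manifest,
    }
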