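"""Pipeline orchestration: simulate -> features -> fit -> evaluate -> map.

One seeded run produces, in its output directory:

* ``plots.csv`` / ``trees.csv`` — the synthetic inventory;
* ``features_<source>.csv`` — plot-level FeatureTable per source (single
  acquisitions and temporal-average combinations);
* ``pearson.csv`` — the correlation screening table;
* ``fits/<feature>_<source>_<model>.json`` — full-data fitted parameters;
* ``report.csv`` / ``report.json`` — LOOCV RMSE / RRMSE (%) / R^2 /
  exceedance per (feature x source x model) cell;
* ``gsv_map.tif`` (optional) — wall-to-wall GSV raster from the chosen fitted
  model, NaN as nodata;
* ``manifest.json`` — config hash, seed, package and library versions.

Partial failures (a cell whose fit fails) are recorded per cell and the run
continues; the run status is "ok", "partial" or "failed".
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__, evaluation, polarimetry, retrieval, synthetic

log = logging.getLogger(__name__)

DEFAULT_COMBINATIONS = (
    ("1",), ("2",), ("3",), ("4",),
    ("1", "4"), ("2", "3"), ("1", "2", "3"), ("2", "3", "4"),
    ("1", "2", "3", "4"),
)
DEFAULT_FEATURES = ("dbl", "dbl_odd", "vol_odd", "dblxvol", "dblxvol_odd")
DEFAULT_MODELS = ("glm", "semiexp")


@dataclass(frozen=True)
class RunConfig:
    """Everything a pipeline run needs; defaults mirror the study design."""

    scene: synthetic.SceneConfig = field(default_factory=synthetic.SceneConfig)
    combinations: tuple[tuple[str, ...], ...] = DEFAULT_COMBINATIONS
    features: tuple[str, ...] = DEFAULT_FEATURES
    models: tuple[str, ...] = DEFAULT_MODELS
    alpha: float = evaluation.DEFAULT_ALPHA
    threshold_rel: float = evaluation.DEFAULT_EXCEED_THRESHOLD
    gsv_cap: float = retrieval.DEFAULT_GSV_CAP
    make_map: bool = False
    map_feature: str = "dblxvol_odd"
    map_model: str = "glm"
    map_source: tuple[str, ...] = ("1", "2", "3", "4")

    def __post_init__(self) -> None:
        if not self.features or not self.models:
            raise ValueError("need at least one feature and one model")
        labels = {a.label for a in self.scene.acquisitions}
        for combo in self.combinations:
            unknown = set(combo) - labels
            if unknown:
                raise ValueError(f"combination {combo} references unknown acquisitions {unknown}")
        bad = set(self.features) - set(polarimetry.ANALYSIS_FEATURES)
        if bad:
            raise ValueError(f"unknown feature(s): {sorted(bad)}")

    def to_dict(self) -> dict:
        return {
            "scene": self.scene.to_dict(),
            "combinations": [list(c) for c in self.combinations],
            "features": list(self.features),
            "models": list(self.models),
            "alpha": self.alpha,
            "threshold_rel": self.threshold_rel,
            "gsv_cap": self.gsv_cap,
            "make_map": self.make_map,
            "map_feature": self.map_feature,
            "map_model": self.map_model,
            "map_source": list(self.map_source),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "scene" in d:
            d["scene"] = synthetic.SceneConfig.from_dict(d["scene"])
        for key in ("combinations",):
            if key in d:
                d[key] = tuple(tuple(c) for c in d[key])
        for key in ("features", "models", "map_source"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def build_source_tables(
    plots, config: "RunConfig"
) -> dict[str, pd.DataFrame]:
    """FeatureTables for every configured source (singles + combinations),
    shadow plots excluded, fused features computed after temporal averaging."""
    raw = synthetic.gen_powers(plots, config.scene)
    keep = [p.id for p in plots if not p.shadow_flag]
    singles = {
        label: polarimetry.fuse_table(
            df[df["plot_id"].isin(keep)].reset_index(drop=True)
        ).assign(source=label)
        for label, df in raw.items()
    }
    out: dict[str, pd.DataFrame] = {}
    for combo in config.combinations:
        label = ",".join(combo)
        if len(combo) == 1:
            out[label] = singles[combo[0]]
        else:
            out[label] = polarimetry.temporal_average(singles, combo)
    return out


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Execute the full synthetic pipeline; returns a summary dict with the
    report DataFrame under "report" and exit status under "status"."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "fits").mkdir(exist_ok=True)

    plots = synthetic.gen_plots(config.scene)
    from .inventory import write_plot_csvs

    write_plot_csvs(plots, outdir / "plots.csv", outdir / "trees.csv")

    tables = build_source_tables(plots, config)
    for label, df in tables.items():
        df.to_csv(outdir / f"features_{label.replace(',', '_')}.csv", index=False)

    corr = evaluation.pearson_table(tables, alpha=config.alpha)
    corr.to_csv(outdir / "pearson.csv", index=False)

    reports: list[evaluation.EvaluationReport] = []
    failures: list[dict] = []
    for feat in config.features:
        for label, df in tables.items():
            sigma = df[feat].to_numpy(dtype=float)
            gsv = df["gsv"].to_numpy(dtype=float)
            for model in config.models:
                cell = {"feature": feat, "source": label, "model": model}
                try:
                    fit = (
                        retrieval.glm_fit(sigma, gsv, feature=feat)
                        if model == "glm"
                        else retrieval.semiexp_fit(sigma, gsv, feature=feat)
                    )
                    fname = f"{feat}_{label.replace(',', '_')}_{model}.json"
                    retrieval.write_fit_json(outdir / "fits" / fname, fit)
                    rep = evaluation.evaluate_cell(
                        sigma, gsv, model, feature=feat, source=label,
                        gsv_cap=config.gsv_cap, threshold_rel=config.threshold_rel,
                    )
                    reports.append(rep)
                    log.info("cell %s: RMSE=%.2f RRMSE=%.2f%% R2=%.3f",
                             cell, rep.rmse, rep.rrmse, rep.r2)
                except (retrieval.FitError, ValueError) as exc:
                    log.warning("cell %s failed: %s", cell, exc)
                    failures.append({**cell, "error": str(exc)})

    report_df = pd.DataFrame([r.to_dict() for r in reports])
    report_df.to_csv(outdir / "report.csv", index=False)
    with open(outdir / "report.json", "w") as fh:
        json.dump([r.to_dict() for r in reports], fh, indent=2)

    if config.make_map:
        _write_map(plots, config, outdir)

    manifest = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.scene.seed,
        "versions": _versions(),
        "n_cells": len(reports),
        "failures": failures,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)

    status = "ok" if not failures else ("partial" if reports else "failed")
    return {"status": status, "report": report_df, "pearson": corr,
            "failures": failures, "outdir": str(outdir)}


def _versions() -> dict:
    import scipy

    return {"polgsv": __version__, "numpy": np.__version__,
            "scipy": scipy.__version__, "pandas": pd.__version__}


# ---------------------------------------------------------------------------
# wall-to-wall GSV mapping
# ---------------------------------------------------------------------------

def map_gsv(
    stack: np.ndarray,
    fit,
    feature: str,
    mask: np.ndarray | None = None,
    gsv_cap: float = retrieval.DEFAULT_GSV_CAP,
    clamp: bool = True,
) -> np.ndarray:
    """Per-pixel GSV raster from a 4-band (odd, dbl, vol, hlx) power stack.

    The fused/base feature is computed per pixel, then inverted through the
    fitted model.  Masked pixels (mask truthy) and non-invertible pixels are
    NaN.  GLM inversions are optionally clamped to [0, gsv_cap] for mapping.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3 or stack.shape[0] < 4:
        raise ValueError("expected a (4, H, W) power stack")
    if mask is not None and mask.shape != stack.shape[1:]:
        raise ValueError("mask grid does not match the power stack")
    odd, dbl, vol = stack[0], stack[1], stack[2]
    with np.errstate(divide="ignore", invalid="ignore"):
        feats = {
            "odd": odd, "dbl": dbl, "vol": vol,
            "dbl_odd": np.where(odd > 0, dbl / np.where(odd > 0, odd, 1.0), np.nan),
            "vol_odd": np.where(odd > 0, vol / np.where(odd > 0, odd, 1.0), np.nan),
            "dblxvol": dbl * vol,
            "dblxvol_odd": np.where(odd > 0, dbl * vol / np.where(odd > 0, odd, 1.0), np.nan),
        }
    if feature not in feats:
        raise ValueError(f"unknown feature {feature!r}")
    sigma = feats[feature]

    if isinstance(fit, retrieval.GLMFit):
        gsv = retrieval.glm_invert(sigma, fit)
        if clamp:
            gsv = np.clip(gsv, 0.0, gsv_cap)
    elif isinstance(fit, retrieval.SemiExpFit):
        gsv, _ = retrieval.semiexp_invert(sigma, fit, gsv_cap=gsv_cap)
    else:
        raise TypeError(f"unsupported fit type {type(fit).__name__}")
    if mask is not None:
        gsv = np.where(mask, np.nan, gsv)
    return gsv


def _write_map(plots, config: RunConfig, outdir: Path) -> None:
    import tifffile

    acq_by_label = {a.label: a for a in config.scene.acquisitions}
    stacks = []
    grid = None
    for lab in config.map_source:
        stack, grid = synthetic.gen_scene_rasters(plots, config.scene, acq_by_label[lab])
        stacks.append(stack)
    mean_stack = np.mean(stacks, axis=0)

    fname = (
        f"{config.map_feature}_{','.join(config.map_source).replace(',', '_')}"
        f"_{config.map_model}.json"
    )
    fit = retrieval.read_fit_json(outdir / "fits" / fname)
    gsv = map_gsv(mean_stack, fit, config.map_feature, gsv_cap=config.gsv_cap)
    tifffile.imwrite(str(outdir / "gsv_map.tif"), gsv.astype(np.float32))
    with open(outdir / "gsv_map.tif.grid.json", "w") as fh:
        json.dump(grid.to_dict(), fh)
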