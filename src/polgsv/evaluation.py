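"""Assessment protocol for GSV retrieval.

Variable screening uses the Pearson product-moment correlation gamma between
each polarimetric characteristic and plot GSV, with a two-tailed t test at a
stated significance level (default alpha = 0.01); the critical |gamma| is
always computed from the actual sample size rather than read from a table.

Model assessment is leave-one-out cross-validation (LOOCV): for each plot the
model is refitted from scratch on the other n-1 plots (including the
semi-exponential initialisation rule) and the held-out power inverted to a
GSV prediction.  Accuracy statistics are

    RMSE   = sqrt(mean (pred - obs)^2)              [m^3/ha]
    RRMSE  = 100 * RMSE / mean(obs)                 [%]
    R^2    = squared Pearson correlation of obs vs pred (default; the
             1 - SSE/SST variant is available via ``r2_method`` but can go
             negative under LOOCV)

plus the fraction of plots whose relative error exceeds a threshold
(default 0.5).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import retrieval
from .polarimetry import ANALYSIS_FEATURES

log = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.01
DEFAULT_EXCEED_THRESHOLD = 0.5


@dataclass(frozen=True)
class EvaluationReport:
    """LOOCV accuracy of one (feature, source, model) cell."""

    feature: str
    source: str
    model: str
    n: int
    rmse: float
    rrmse: float
    r2: float
    exceed_frac: float
    exceed_threshold: float
    n_failed_folds: int = 0

    def to_dict(self) -> dict:
        return {
            "feature": self.feature, "source": self.source, "model": self.model,
            "n": self.n, "rmse": self.rmse, "rrmse": self.rrmse, "r2": self.r2,
            "exceed_frac": self.exceed_frac,
            "exceed_threshold": self.exceed_threshold,
            "n_failed_folds": self.n_failed_folds,
        }


# ---------------------------------------------------------------------------
# correlation screening
# ---------------------------------------------------------------------------

def critical_r(n: int, alpha: float = DEFAULT_ALPHA) -> float:
    """Two-tailed critical |gamma| for a Pearson correlation at sample size n."""
    if n < 3:
        raise ValueError("need n >= 3 for a correlation test")
    t = stats.t.ppf(1.0 - alpha / 2.0, n - 2)
    return float(t / np.sqrt(t**2 + n - 2))


def pearson_table(
    tables: Mapping[str, pd.DataFrame],
    gsv: pd.Series | Mapping[str, float] | None = None,
    features: Sequence[str] = tuple(ANALYSIS_FEATURES),
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Correlation of each feature with GSV per source.

    ``tables`` maps source label -> FeatureTable (must contain plot_id and the
    feature columns; GSV is taken from the table's ``gsv`` column unless a
    separate per-plot mapping is given).  Shadow-flagged plots are assumed
    already excluded.  Zero-variance features yield a missing gamma.

    Returns a DataFrame with columns source, feature, gamma, n, p_value,
    critical_r, significant.
    """
    rows = []
    for source, df in tables.items():
        if gsv is None:
            g_all = df["gsv"].to_numpy(dtype=float)
        else:
            gm = gsv if isinstance(gsv, Mapping) else gsv.to_dict()
            g_all = np.array([gm[p] for p in df["plot_id"]], dtype=float)
        for feat in features:
            x = df[feat].to_numpy(dtype=float)
            ok = np.isfinite(x) & np.isfinite(g_all)
            n = int(ok.sum())
            if n < 3 or np.ptp(x[ok]) == 0 or np.ptp(g_all[ok]) == 0:
                rows.append({"source": source, "feature": feat, "gamma": np.nan,
                             "n": n, "p_value": np.nan, "critical_r": np.nan,
                             "significant": False})
                continue
            r, p = stats.pearsonr(x[ok], g_all[ok])
            rc = critical_r(n, alpha)
            rows.append({"source": source, "feature": feat, "gamma": float(r),
                         "n": n, "p_value": float(p), "critical_r": rc,
                         "significant": bool(abs(r) >= rc)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# LOOCV
# ---------------------------------------------------------------------------

def loocv(
    sigma,
    gsv,
    model: str,
    gsv_cap: float = retrieval.DEFAULT_GSV_CAP,
    feature: str = "",
) -> tuple[np.ndarray, int]:
    """Leave-one-out predictions.

    For each plot i the chosen model ("glm" or "semiexp") is refitted on the
    remaining plots and the held-out sigma_i inverted to GSV.  Returns
    (predictions aligned with the input order, number of failed folds); a
    failed fold leaves NaN in its slot.
    """
    s = np.asarray(sigma, dtype=float)
    g = np.asarray(gsv, dtype=float)
    if s.shape != g.shape:
        raise ValueError("sigma and gsv must have the same length")
    n = s.size
    if n < 4:
        raise ValueError("LOOCV needs at least 4 plots")
    if model not in ("glm", "semiexp"):
        raise ValueError(f"unknown model {model!r}")

    pred = np.full(n, np.nan)
    failed = 0
    flagged = 0
    idx = np.arange(n)
    for i in range(n):
        rest = idx != i
        try:
            if model == "glm":
                fit = retrieval.glm_fit(s[rest], g[rest], feature=feature)
                pred[i] = retrieval.glm_invert(float(s[i]), fit)
            else:
                fit = retrieval.semiexp_fit(s[rest], g[rest], feature=feature)
                flagged += int(not fit.converged)
                pred[i], _ = retrieval.semiexp_invert(float(s[i]), fit, gsv_cap=gsv_cap)
        except retrieval.FitError:
            failed += 1
    if failed:
        log.warning("LOOCV: %d of %d folds failed", failed, n)
    if flagged:
        log.warning("LOOCV: %d of %d semi-exponential folds flagged "
                    "(non-convergence or k at bound)", flagged, n)
    return pred, failed


# ---------------------------------------------------------------------------
# accuracy statistics
# ---------------------------------------------------------------------------

def metrics(
    observed, predicted, r2_method: str = "pearson"
) -> tuple[float, float, float]:
    """(RMSE m^3/ha, RRMSE %, R^2) over pairs where both values are finite."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError("observed and predicted must have the same length")
    ok = np.isfinite(obs) & np.isfinite(pred)
    obs, pred = obs[ok], pred[ok]
    if obs.size < 2:
        raise ValueError("need >= 2 usable pairs")
    rmse = float(np.sqrt(np.mean((pred - obs) ** 2)))
    mean_obs = float(obs.mean())
    if mean_obs == 0:
        raise ValueError("mean observed GSV is zero: RRMSE undefined")
    rrmse = 100.0 * rmse / mean_obs
    if r2_method == "pearson":
        if np.ptp(obs) == 0 or np.ptp(pred) == 0:
            r2 = float("nan")
        else:
            r2 = float(stats.pearsonr(obs, pred)[0] ** 2)
    elif r2_method == "ss":
        sst = float(((obs - obs.mean()) ** 2).sum())
        r2 = 1.0 - float(((pred - obs) ** 2).sum()) / sst if sst > 0 else float("nan")
    else:
        raise ValueError(f"unknown r2_method {r2_method!r}")
    return rmse, rrmse, r2


def exceedance(observed, predicted, threshold_rel: float = DEFAULT_EXCEED_THRESHOLD) -> float:
    """Fraction of plots with |pred - obs| / obs above the relative threshold."""
    if not threshold_rel > 0:
        raise ValueError("threshold_rel must be positive")
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    ok = np.isfinite(obs) & np.isfinite(pred) & (obs != 0)
    n_dropped = int(obs.size - ok.sum())
    if n_dropped:
        log.info("exceedance: dropped %d pair(s) with zero/missing observed GSV", n_dropped)
    if ok.sum() == 0:
        raise ValueError("no usable pairs for exceedance")
    rel = np.abs(pred[ok] - obs[ok]) / obs[ok]
    return float(np.mean(rel > threshold_rel))


def evaluate_cell(
    sigma,
    gsv,
    model: str,
    feature: str = "",
    source: str = "",
    gsv_cap: float = retrieval.DEFAULT_GSV_CAP,
    threshold_rel: float = DEFAULT_EXCEED_THRESHOLD,
) -> EvaluationReport:
    """LOOCV + metrics + exceedance for one (feature, source, model) cell."""
    pred, failed = loocv(sigma, gsv, model, gsv_cap=gsv_cap, feature=feature)
    rmse, rrmse, r2 = metrics(gsv, pred)
    exc = exceedance(gsv, pred, threshold_rel)
    return EvaluationReport(
        feature=feature, source=source, model=model,
        n=int(np.asarray(gsv).size), rmse=rmse, rrmse=rrmse, r2=r2,
        exceed_frac=exc, exceed_threshold=threshold_rel, n_failed_folds=failed,
    )


# ---------------------------------------------------------------------------
# correlation-table aggregation
# ---------------------------------------------------------------------------

def round_half_up(x: float, decimals: int = 3) -> float:
    """Decimal half-up rounding (report convention; banker's rounding would
    disagree on exact ties)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def aggregate_correlations(
    table: pd.DataFrame,
    sources: Sequence[str],
    rule: str = "all",
    decimals: int = 3,
) -> pd.Series:
    """Mean gamma per feature over the named (single-acquisition) sources.

    ``rule='significant_only'`` drops entries whose significance flag is not
    set before averaging; a feature with nothing left is reported missing.
    Results are rounded half-up to ``decimals`` for report output.
    """
    if rule not in ("all", "significant_only"):
        raise ValueError(f"unknown rule {rule!r}")
    missing = set(sources) - set(table["source"])
    if missing:
        raise ValueError(f"sources absent from table: {sorted(missing)}")
    sub = table[table["source"].isin(list(sources))]
    if rule == "significant_only":
        sub = sub[sub["significant"].astype(bool)]
    out = {}
    for feat in table["feature"].unique():
        vals = sub.loc[sub["feature"] == feat, "gamma"].dropna()
        if not len(vals):
            out[feat] = float("nan")
            continue
        # decimal-arithmetic mean: gammas originate from printed decimals, and
        # a binary mean can fall a ulp below an exact decimal tie (e.g. the
        # mean of 0.437 and 0.360 must round 0.3985 -> 0.399)
        mean = sum(Decimal(repr(float(v))) for v in vals) / len(vals)
        q = Decimal(1).scaleb(-decimals)
        out[feat] = float(mean.quantize(q, rounding=ROUND_HALF_UP))
    return pd.Series(out, name=f"mean_gamma_{rule}")


def format_report_table(reports: Sequence[EvaluationReport]) -> pd.DataFrame:
    """Published-style layout: rows = source, columns = (model, statistic),
    gamma-style values to 3 decimals, RMSE/RRMSE to 2 (half-up)."""
    df = pd.DataFrame([r.to_dict() for r in reports])
    df["rmse"] = df["rmse"].map(lambda v: round_half_up(v, 2))
    df["rrmse"] = df["rrmse"].map(lambda v: round_half_up(v, 2))
    df["r2"] = df["r2"].map(lambda v: round_half_up(v, 3))
    return df.pivot_table(
        index=["feature", "source"], columns="model",
        values=["rmse", "rrmse", "r2"], sort=False,
    )
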