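"""Retrieval models mapping a polarimetric characteristic to GSV.

Two single-predictor models are supported.

Exponential general linear model (GLM)
    sigma = exp(a0 + a1 * GSV)
fitted through the natural-log link, ln(sigma) = a0 + a1 * GSV, by ordinary
least squares — no initial values needed.  Inversion
    GSV = (ln(sigma) - a0) / a1
is monotone in sigma and unbounded: the model has no hard saturation level,
which is what makes it usable in high-GSV stands.

Semi-exponential (water-cloud-type) saturation model
    sigma = beta_s + (beta_n - beta_s) * exp(-GSV / k)
where beta_n is the power of non-vegetated ground (GSV = 0), beta_s the
asymptotic power of the densest forest, and k (m^3/ha) the saturation
constant.  (Some printings of this model show exp(GSV - k); that form
contradicts both boundary conditions sigma(0) = beta_n and
sigma(inf) -> beta_s and is treated here as an erratum for the standard
water-cloud exponent.)  Fitted by nonlinear least squares with range-based
initial values; inversion
    GSV = -k * ln((sigma - beta_s) / (beta_n - beta_s))
is only defined while sigma lies strictly between the two asymptotes, so
predictions saturate at a configurable cap for sigma at or beyond beta_s.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, asdict

import numpy as np
from scipy import optimize, stats

log = logging.getLogger(__name__)

DEFAULT_GSV_CAP = 500.0  # m^3/ha, just above the densest stands modelled
_SEMIEXP_XTOL = 1e-10
_SEMIEXP_MAX_NFEV = 500
_SEMIEXP_RESTARTS = 5

#: prediction flags
FLAG_OK = 0
FLAG_SATURATED = 1   # sigma at/beyond the dense-forest asymptote -> cap
FLAG_BELOW_ZERO = 2  # sigma beyond the bare-ground value -> 0
FLAG_MISSING = 3     # sigma non-positive / NaN, or failed fit


class FitError(ValueError):
    """Raised when a retrieval model cannot be fitted on the given data."""


@dataclass(frozen=True)
class GLMFit:
    """Fitted exponential GLM: ln sigma = a0 + a1 * GSV."""

    a0: float
    a1: float
    feature: str = ""
    n_used: int = 0
    n_excluded: int = 0
    resid_sd_log: float = float("nan")

    def to_dict(self) -> dict:
        return {"model": "glm", **asdict(self)}


@dataclass(frozen=True)
class SemiExpFit:
    """Fitted semi-exponential model: sigma = beta_s + (beta_n - beta_s) e^{-GSV/k}."""

    beta_n: float
    beta_s: float
    k: float
    feature: str = ""
    n_used: int = 0
    converged: bool = True
    n_restarts: int = 0
    at_bound: bool = False
    cost: float = float("nan")

    def to_dict(self) -> dict:
        return {"model": "semiexp", **asdict(self)}

    def predict(self, gsv) -> np.ndarray:
        g = np.asarray(gsv, dtype=float)
        return self.beta_s + (self.beta_n - self.beta_s) * np.exp(-g / self.k)


def _clean_pairs(sigma, gsv) -> tuple[np.ndarray, np.ndarray, int]:
    s = np.asarray(sigma, dtype=float)
    g = np.asarray(gsv, dtype=float)
    if s.shape != g.shape:
        raise ValueError("sigma and gsv must have the same length")
    ok = np.isfinite(s) & np.isfinite(g) & (s > 0)
    n_excl = int(s.size - ok.sum())
    if n_excl:
        log.info("excluded %d non-positive/missing sigma value(s) from fit", n_excl)
    return s[ok], g[ok], n_excl


# ---------------------------------------------------------------------------
# exponential GLM
# ---------------------------------------------------------------------------

def glm_fit(sigma, gsv, feature: str = "") -> GLMFit:
    """OLS of ln(sigma) on GSV (log link); exact on noise-free data."""
    s, g, n_excl = _clean_pairs(sigma, gsv)
    if s.size < 3:
        raise FitError(f"need >= 3 usable pairs, got {s.size}")
    if np.ptp(g) == 0:
        raise FitError("all GSV values identical: slope unidentifiable")
    res = stats.linregress(g, np.log(s))
    resid = np.log(s) - (res.intercept + res.slope * g)
    dof = max(s.size - 2, 1)
    return GLMFit(
        a0=float(res.intercept),
        a1=float(res.slope),
        feature=feature,
        n_used=int(s.size),
        n_excluded=n_excl,
        resid_sd_log=float(np.sqrt((resid**2).sum() / dof)),
    )


def glm_invert(sigma, fit: GLMFit):
    """GSV = (ln sigma - a0) / a1; NaN where sigma is non-positive."""
    if fit.a1 == 0:
        raise FitError("a1 = 0: GLM inversion undefined")
    s = np.asarray(sigma, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(s > 0, (np.log(np.where(s > 0, s, 1.0)) - fit.a0) / fit.a1, np.nan)
    return float(out) if np.isscalar(sigma) else out


# ---------------------------------------------------------------------------
# semi-exponential saturation model
# ---------------------------------------------------------------------------

def _semiexp_initial(s: np.ndarray, g: np.ndarray) -> tuple[float, float, float]:
    """Range-based starting values: beta_n from the 10% least-vegetated
    (lowest-GSV) plots, beta_s from the 10% densest, k at the median GSV."""
    order = np.argsort(g)
    n10 = max(1, int(round(0.1 * g.size)))
    beta_n0 = float(s[order[:n10]].mean())
    beta_s0 = float(s[order[-n10:]].mean())
    if beta_n0 == beta_s0:
        beta_s0 = beta_n0 * (1.0 + 1e-3) + 1e-9
    return beta_n0, beta_s0, float(np.median(g))


def semiexp_fit(sigma, gsv, feature: str = "") -> SemiExpFit:
    """Nonlinear least squares for (beta_n, beta_s, k), k > 0.

    Up to 5 jittered restarts on non-convergence; a fit that still fails or
    ends with k pinned at its bound is returned flagged (``converged`` /
    ``at_bound``), never silently.
    """
    s, g, _ = _clean_pairs(sigma, gsv)
    if s.size < 4:
        raise FitError(f"need >= 4 usable pairs, got {s.size}")
    if np.unique(g).size < 2:
        raise FitError("need > 1 distinct GSV value")

    k_lo, k_hi = 1e-3, 1e6

    def resid(p):
        bn, bs, k = p
        return bs + (bn - bs) * np.exp(-g / k) - s

    def jac(p):
        bn, bs, k = p
        e = np.exp(-g / k)
        return np.column_stack([e, 1.0 - e, (bn - bs) * e * g / k**2])

    x0 = np.array(_semiexp_initial(s, g))
    x0[2] = min(max(x0[2], k_lo * 10), k_hi / 10)
    rng = np.random.default_rng(0)  # deterministic restart jitter
    best = None
    n_restarts = 0
    for attempt in range(1 + _SEMIEXP_RESTARTS):
        start = x0.copy() if attempt == 0 else x0 * (1.0 + 0.2 * rng.standard_normal(3))
        start[2] = min(max(abs(start[2]), k_lo * 10), k_hi / 10)
        try:
            sol = optimize.least_squares(
                resid,
                start,
                jac=jac,
                bounds=([-np.inf, -np.inf, k_lo], [np.inf, np.inf, k_hi]),
                method="trf",
                xtol=_SEMIEXP_XTOL,
                ftol=_SEMIEXP_XTOL,
                gtol=_SEMIEXP_XTOL,
                max_nfev=_SEMIEXP_MAX_NFEV,
            )
        except Exception:  # singular jacobian etc. -> restart with jitter
            sol = None
        if sol is not None and (best is None or sol.cost < best.cost):
            best = sol
        if sol is not None and sol.success:
            break
        n_restarts = attempt + 1

    if best is None:
        raise FitError("semi-exponential fit failed on every restart")
    bn, bs, k = (float(v) for v in best.x)
    at_bound = bool(k <= k_lo * (1 + 1e-6) or k >= k_hi * (1 - 1e-6))
    converged = bool(best.success and not at_bound)
    if not converged:
        # downstream consumers check the flags; a cell-level WARN is emitted
        # by the pipeline, not per fit
        log.info("semi-exponential fit flagged (converged=%s, at_bound=%s)",
                 best.success, at_bound)
    if bn == bs:
        raise FitError("degenerate fit: beta_n == beta_s")
    return SemiExpFit(
        beta_n=bn, beta_s=bs, k=k, feature=feature, n_used=int(s.size),
        converged=converged, n_restarts=n_restarts, at_bound=at_bound,
        cost=float(best.cost),
    )


def semiexp_invert(
    sigma, fit: SemiExpFit, gsv_cap: float = DEFAULT_GSV_CAP
) -> tuple[np.ndarray, np.ndarray]:
    """Invert the saturation model.

    Returns (gsv, flags).  For each sigma, with r = (sigma - beta_s) /
    (beta_n - beta_s):  r in (0, 1] -> GSV = -k ln r;  r <= 0 (at/beyond the
    dense-forest asymptote) -> ``gsv_cap`` flagged SATURATED;  r > 1 (beyond
    the bare-ground power) -> 0 flagged BELOW_ZERO.
    """
    if fit.beta_n == fit.beta_s or not fit.k > 0:
        raise FitError("invalid semi-exponential fit for inversion")
    s = np.asarray(sigma, dtype=float)
    scalar = s.ndim == 0
    s = np.atleast_1d(s)
    r = (s - fit.beta_s) / (fit.beta_n - fit.beta_s)
    gsv = np.full(s.shape, np.nan)
    flags = np.full(s.shape, FLAG_MISSING, dtype=int)

    ok = np.isfinite(r)
    mid = ok & (r > 0) & (r <= 1)
    with np.errstate(divide="ignore"):
        gsv[mid] = -fit.k * np.log(r[mid])
    flags[mid] = FLAG_OK
    sat = ok & (r <= 0)
    gsv[sat] = gsv_cap
    flags[sat] = FLAG_SATURATED
    low = ok & (r > 1)
    gsv[low] = 0.0
    flags[low] = FLAG_BELOW_ZERO
    if scalar:
        return float(gsv[0]), int(flags[0])
    return gsv, flags


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def write_fit_json(path, fit: GLMFit | SemiExpFit) -> None:
    with open(path, "w") as fh:
        json.dump(fit.to_dict(), fh, indent=2)


def read_fit_json(path) -> GLMFit | SemiExpFit:
    with open(path) as fh:
        d = json.load(fh)
    model = d.pop("model")
    if model == "glm":
        return GLMFit(**d)
    if model == "semiexp":
        return SemiExpFit(**d)
    raise ValueError(f"unknown model {model!r}")
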