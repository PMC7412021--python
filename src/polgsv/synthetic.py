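"""Synthetic scene generator for stand-level GSV retrieval experiments.

No polarimetric field campaign data accompany this package, so every
downstream stage (decomposition, feature fusion, model fitting, LOOCV
assessment) is exercised on synthetic scenes whose statistical structure
mirrors the study design the pipeline targets:

* ~50 square inventory plots of planted conifer forest with growing stock
  volume (GSV) between roughly 60 and 450 m^3/ha, drawn from a three-stratum
  age-class mixture (young / immature / mature with weights 10 / 52 / 38 %);
* four quad-pol acquisitions within one growing season, each carrying its own
  log-power bias and extra noise standard deviation standing in for ground
  moisture and wind disturbance on the acquisition date;
* per-characteristic log-linear power laws ln(sigma) = a0 + a1 * GSV, the
  generative counterpart of the exponential retrieval model, with signs
  matching L-band phenomenology: double-bounce increases with GSV, surface
  scattering decreases, volume scattering increases weakly, helix power is
  negligible over forest;
* multiplicative speckle, optionally, as a complex-Wishart multilook draw on
  reconstructed coherency matrices.

Default bias/noise magnitudes are calibrated so that single-acquisition
Pearson correlations between the characteristics and GSV land in the ranges
published for L-band quad-pol plantation studies (|gamma| roughly 0.2-0.7,
weakest for the two rain-affected mid-season acquisitions).

Randomness: one root seed; ``numpy.random.SeedSequence(seed).spawn`` assigns
fixed child streams (0: plots, 1: powers, 2: T3/speckle, 3: rasters,
4: shadow flags), so each operation is reproducible independently of the
others.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .inventory import PlotRecord, TaperModel, TreeRecord, plot_gsv

CHARACTERISTICS = ("odd", "dbl", "vol", "hlx")

#: raster layout constants: plots sit at the centres of non-overlapping
#: window-sized tiles so that window extraction sees a constant neighbourhood
PIXEL_SIZE_M = 10.0
TILE_PIX = 7


@dataclass(frozen=True)
class GSVLaw:
    """Mixture of uniform GSV strata: ((weight, low, high), ...) in m^3/ha."""

    strata: tuple[tuple[float, float, float], ...] = (
        (0.10, 60.0, 130.0),   # young
        (0.52, 130.0, 280.0),  # immature
        (0.38, 250.0, 450.0),  # mature
    )

    def __post_init__(self) -> None:
        w = sum(s[0] for s in self.strata)
        if not math.isclose(w, 1.0, rel_tol=1e-9):
            raise ValueError(f"stratum weights must sum to 1, got {w}")
        for _, lo, hi in self.strata:
            if hi < lo or lo < 0:
                raise ValueError(f"invalid stratum bounds ({lo}, {hi})")

    @classmethod
    def constant(cls, value: float) -> "GSVLaw":
        return cls(strata=((1.0, value, value),))

    @property
    def is_degenerate(self) -> bool:
        lows = [lo for _, lo, _ in self.strata]
        highs = [hi for _, _, hi in self.strata]
        return min(lows) == max(highs)

    def mean(self) -> float:
        return sum(w * (lo + hi) / 2.0 for w, lo, hi in self.strata)

    def var(self) -> float:
        m = self.mean()
        second = sum(
            w * ((hi - lo) ** 2 / 12.0 + ((lo + hi) / 2.0) ** 2)
            for w, lo, hi in self.strata
        )
        return second - m * m

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        weights = np.array([s[0] for s in self.strata])
        idx = rng.choice(len(self.strata), size=n, p=weights)
        lo = np.array([s[1] for s in self.strata])[idx]
        hi = np.array([s[2] for s in self.strata])[idx]
        return rng.uniform(lo, hi)


@dataclass(frozen=True)
class AcquisitionMeta:
    """One SAR acquisition: a label, per-characteristic log-power bias
    (moisture/wind disturbance on that date) and extra noise SD."""

    label: str
    date: str = ""
    bias: Mapping[str, float] = field(default_factory=dict)
    extra_noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.extra_noise_sd < 0:
            raise ValueError("extra_noise_sd must be >= 0")
        for c, b in self.bias.items():
            if c not in CHARACTERISTICS:
                raise ValueError(f"unknown characteristic {c!r} in bias")
            if not math.isfinite(b):
                raise ValueError(f"bias for {c!r} must be finite")


def default_acquisitions() -> tuple[AcquisitionMeta, ...]:
    """Four growing-season acquisitions; the two mid-season dates are
    rain-affected (higher moisture bias on surface power, extra noise)."""
    wet = {"odd": 0.15, "dbl": -0.10, "vol": 0.05}
    return (
        AcquisitionMeta("1", "06-30", bias={}, extra_noise_sd=0.0),
        AcquisitionMeta("2", "07-14", bias=dict(wet), extra_noise_sd=0.35),
        AcquisitionMeta("3", "08-25", bias=dict(wet), extra_noise_sd=0.35),
        AcquisitionMeta("4", "09-22", bias={"odd": 0.05, "dbl": -0.05}, extra_noise_sd=0.15),
    )


#: per-characteristic (a0_true, a1_true): intercept of ln power and slope per
#: (m^3/ha).  Signs: Dbl positive, Odd negative, Vol weakly positive, Hlx flat.
DEFAULT_POWER_LAW: dict[str, tuple[float, float]] = {
    "odd": (-0.2, -0.0025),
    "dbl": (-2.2, 0.0030),
    "vol": (-1.5, 0.0012),
    "hlx": (-4.6, 0.0),
}


@dataclass(frozen=True)
class SceneConfig:
    """Full specification of a synthetic scene (defaults = study conditions)."""

    n_plots: int = 50
    gsv_law: GSVLaw = field(default_factory=GSVLaw)
    acquisitions: tuple[AcquisitionMeta, ...] = field(default_factory=default_acquisitions)
    power_law: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_POWER_LAW)
    )
    noise_sd: float = 0.35
    looks: int | None = None  # None: speckle disabled (plot-level tables)
    shadow_frac: float = 0.0
    plot_side_m: float = 30.0
    taper_f: float = 0.45
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_plots < 3:
            raise ValueError("n_plots must be >= 3")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.looks is not None and self.looks < 1:
            raise ValueError("looks must be >= 1")
        if not 0.0 <= self.shadow_frac < 1.0:
            raise ValueError("shadow_frac must lie in [0, 1)")
        missing = set(CHARACTERISTICS) - set(self.power_law)
        if missing:
            raise ValueError(f"power_law missing characteristics: {sorted(missing)}")

    @property
    def taper(self) -> TaperModel:
        return TaperModel.constant(self.taper_f)

    def streams(self) -> dict[str, np.random.Generator]:
        kids = np.random.SeedSequence(self.seed).spawn(5)
        names = ("plots", "powers", "t3", "rasters", "shadow")
        return {n: np.random.default_rng(k) for n, k in zip(names, kids)}

    def to_dict(self) -> dict:
        d = asdict(self)
        d["gsv_law"] = [list(s) for s in self.gsv_law.strata]
        d["acquisitions"] = [
            {"label": a.label, "date": a.date, "bias": dict(a.bias),
             "extra_noise_sd": a.extra_noise_sd}
            for a in self.acquisitions
        ]
        d["power_law"] = {c: list(v) for c, v in self.power_law.items()}
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SceneConfig":
        d = dict(d)
        if "gsv_law" in d:
            d["gsv_law"] = GSVLaw(strata=tuple(tuple(s) for s in d["gsv_law"]))
        if "acquisitions" in d:
            d["acquisitions"] = tuple(
                AcquisitionMeta(**a) if isinstance(a, Mapping) else a
                for a in d["acquisitions"]
            )
        if "power_law" in d:
            d["power_law"] = {c: tuple(v) for c, v in d["power_law"].items()}
        return cls(**d)


# ---------------------------------------------------------------------------
# plot generation
# ---------------------------------------------------------------------------

def _height_from_dbh(dbh: np.ndarray) -> np.ndarray:
    # monotone DBH-height curve tuned to conifer plantations
    # (H about 20.5 m at DBH 29.5 cm)
    return 1.3 + 0.93 * dbh**0.9


def _make_tree_list(
    rng: np.random.Generator, target_gsv: float, area_ha: float, taper_f: float
) -> list[TreeRecord]:
    """Draw a tree list whose summed stem volume matches target_gsv * area.

    Stand structure: mean DBH grows with stand GSV; tree count follows from
    the mean single-tree volume.  An exact match is then obtained by scaling
    all DBH values by sqrt(target/current) (stem volume is quadratic in DBH at
    fixed height), keeping the drawn heights.
    """
    if target_gsv <= 0:
        return []
    frac = np.clip((target_gsv - 60.0) / 390.0, 0.0, 1.0)
    mean_dbh = 10.0 + 16.0 * frac
    mean_h = float(_height_from_dbh(np.array(mean_dbh)))
    v_mean = math.pi * (mean_dbh / 200.0) ** 2 * (mean_h + 3.0) * taper_f
    n = max(3, int(round(target_gsv * area_ha / v_mean)))

    for _ in range(8):
        dbh = rng.normal(mean_dbh, 0.18 * mean_dbh, size=n)
        dbh = np.clip(dbh, 7.0, None)
        h = _height_from_dbh(dbh)
        vol = np.pi * (dbh / 200.0) ** 2 * (h + 3.0) * taper_f
        current = vol.sum() / area_ha
        t = math.sqrt(target_gsv / current)
        if (dbh * t).min() >= 5.0:
            dbh = dbh * t
            return [TreeRecord(float(d), float(hh)) for d, hh in zip(dbh, h)]
    raise RuntimeError("tree-list construction failed to respect the 5 cm DBH floor")


def gen_plots(config: SceneConfig) -> list[PlotRecord]:
    """Generate seeded plots with tree lists reproducing each true GSV.

    Plot centres are laid out on a lattice of non-overlapping 7x7-pixel tiles
    (10 m pixels) so that raster window extraction sees one plot per window.
    """
    if config.gsv_law.is_degenerate and config.n_plots > 1:
        raise ValueError(
            "degenerate (zero-width) GSV law with more than one plot: "
            "downstream correlations are undefined"
        )
    rngs = config.streams()
    rng = rngs["plots"]
    gsv = config.gsv_law.sample(rng, config.n_plots)

    n_shadow = int(round(config.shadow_frac * config.n_plots))
    shadow_idx = set(
        rngs["shadow"].choice(config.n_plots, size=n_shadow, replace=False).tolist()
    ) if n_shadow else set()

    ncol = math.ceil(math.sqrt(config.n_plots))
    tile_m = TILE_PIX * PIXEL_SIZE_M
    plots: list[PlotRecord] = []
    for i in range(config.n_plots):
        r, c = divmod(i, ncol)
        x = (c + 0.5) * tile_m - PIXEL_SIZE_M / 2.0
        y = -((r + 0.5) * tile_m - PIXEL_SIZE_M / 2.0)
        area_ha = config.plot_side_m**2 / 10_000.0
        trees = _make_tree_list(rng, float(gsv[i]), area_ha, config.taper_f)
        p = PlotRecord(
            id=f"P{i + 1:03d}",
            x=x,
            y=y,
            side=config.plot_side_m,
            trees=trees,
            shadow_flag=i in shadow_idx,
        )
        p.gsv = plot_gsv(p, config.taper)
        plots.append(p)
    return plots


# ---------------------------------------------------------------------------
# power generation
# ---------------------------------------------------------------------------

def gen_powers(
    plots: Sequence[PlotRecord], config: SceneConfig
) -> dict[str, pd.DataFrame]:
    """Per-acquisition plot-level decomposition powers from the log-linear law.

    ln sigma_c = a0_true(c) + a1_true(c) * GSV + bias_t(c) + eps,
    eps ~ N(0, noise_sd^2 + extra_noise_sd_t^2), independent across plots,
    acquisitions and characteristics.

    Returns {acquisition label: DataFrame(plot_id, gsv, odd, dbl, vol, hlx)}.
    """
    rng = config.streams()["powers"]
    gsv = np.array([p.gsv for p in plots], dtype=float)
    ids = [p.id for p in plots]
    out: dict[str, pd.DataFrame] = {}
    for acq in config.acquisitions:
        sd = math.sqrt(config.noise_sd**2 + acq.extra_noise_sd**2)
        cols: dict[str, np.ndarray] = {}
        for c in CHARACTERISTICS:
            a0, a1 = config.power_law[c]
            mu = a0 + a1 * gsv + acq.bias.get(c, 0.0)
            eps = rng.normal(0.0, sd, size=len(gsv)) if sd > 0 else 0.0
            cols[c] = np.exp(mu + eps)
        df = pd.DataFrame({"plot_id": ids, "gsv": gsv, **cols})
        out[acq.label] = df
    return out


# ---------------------------------------------------------------------------
# coherency-matrix reconstruction and speckle
# ---------------------------------------------------------------------------

#: canonical unit-trace coherency bases (Pauli basis: [surface, dihedral,
#: cross-pol]); volume = random-dipole cloud, helix = left/right circular pair
T_SURF = np.diag([1.0, 0.0, 0.0]).astype(complex)
T_DBL = np.diag([0.0, 1.0, 0.0]).astype(complex)
T_VOL = np.diag([0.5, 0.25, 0.25]).astype(complex)
T_HLX = 0.5 * np.array(
    [[0.0, 0.0, 0.0], [0.0, 1.0, 1.0j], [0.0, -1.0j, 1.0]], dtype=complex
)


def _wishart_multilook(T: np.ndarray, looks: int, rng: np.random.Generator) -> np.ndarray:
    """L-look sample coherency matrix: (1/L) sum_k u_k u_k^H, u ~ CN(0, T)."""
    jitter = 1e-12 * max(np.trace(T).real, 1.0)
    A = np.linalg.cholesky(T + jitter * np.eye(3))
    z = (rng.standard_normal((looks, 3)) + 1j * rng.standard_normal((looks, 3))) / np.sqrt(2.0)
    u = z @ A.T  # u_k = A z_k, so E[u u^H] = T
    return np.einsum("ki,kj->ij", u, u.conj()) / looks


def gen_t3(
    powers: np.ndarray,
    looks: int | None = None,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Reconstruct coherency matrices from (odd, dbl, vol, hlx) powers.

    ``powers``: array of shape (..., 4), all entries >= 0.  Returns complex
    array of shape (..., 3, 3).  With ``looks`` set, each matrix is replaced
    by a complex-Wishart multilook draw with that equivalent number of looks
    (mean preserved; trace equals the power sum only in expectation).
    """
    powers = np.asarray(powers, dtype=float)
    if powers.shape[-1] != 4:
        raise ValueError("powers must have last dimension 4 (odd, dbl, vol, hlx)")
    if np.any(powers < 0):
        raise ValueError("negative input power: generator contract violated")
    T = (
        powers[..., 0, None, None] * T_SURF
        + powers[..., 1, None, None] * T_DBL
        + powers[..., 2, None, None] * T_VOL
        + powers[..., 3, None, None] * T_HLX
    )
    if looks is None:
        return T
    if looks < 1:
        raise ValueError("looks must be >= 1")
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    flat = T.reshape(-1, 3, 3)
    out = np.empty_like(flat)
    for i in range(flat.shape[0]):
        out[i] = _wishart_multilook(flat[i], int(looks), rng)
    return out.reshape(T.shape)


# ---------------------------------------------------------------------------
# raster scene
# ---------------------------------------------------------------------------

def gen_scene_rasters(
    plots: Sequence[PlotRecord],
    config: SceneConfig,
    acquisition: AcquisitionMeta,
    pixel_noise_sd: float = 0.0,
) -> tuple[np.ndarray, "Grid"]:
    """Render a 4-band (odd, dbl, vol, hlx) power raster for one acquisition.

    The scene is a lattice of 7x7-pixel tiles (10 m pixels).  Tiles holding a
    plot carry that plot's GSV as a constant latent field; empty tiles get a
    random GSV from the scene law.  Per-pixel powers follow the same
    log-linear law as :func:`gen_powers`; ``pixel_noise_sd`` adds independent
    log-normal pixel noise (0 = noise-free, making window means exact).
    """
    from .polarimetry import Grid  # local import to avoid a cycle

    rng = config.streams()["rasters"]
    ncol = math.ceil(math.sqrt(len(plots)))
    nrow = math.ceil(len(plots) / ncol)
    H, W = nrow * TILE_PIX, ncol * TILE_PIX
    latent = config.gsv_law.sample(rng, nrow * ncol).reshape(nrow, ncol)
    for i, p in enumerate(plots):
        r, c = divmod(i, ncol)
        latent[r, c] = p.gsv
    gsv_field = np.kron(latent, np.ones((TILE_PIX, TILE_PIX)))

    bands = []
    for c in CHARACTERISTICS:
        a0, a1 = config.power_law[c]
        mu = a0 + a1 * gsv_field + acquisition.bias.get(c, 0.0)
        if pixel_noise_sd > 0:
            mu = mu + rng.normal(0.0, pixel_noise_sd, size=gsv_field.shape)
        bands.append(np.exp(mu))
    stack = np.stack(bands, axis=0)
    grid = Grid(x0=0.0, y0=0.0, dx=PIXEL_SIZE_M, dy=PIXEL_SIZE_M)
    return stack, grid
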