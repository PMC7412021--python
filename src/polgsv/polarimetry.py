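"""Polarimetric characteristics: Yamaguchi-4 decomposition, fused ratios,
plot window extraction and temporal averaging.

The four-component model-based decomposition splits a 3x3 Pauli-basis
coherency matrix T into surface (Odd), double-bounce (Dbl), volume (Vol) and
helix (Hlx) scattering powers with P_Odd + P_Dbl + P_Vol + P_Hlx = trace(T).
Helix power is read from Im(T23); the volume contribution is scaled from the
cross-pol channel T33 using one of three canonical volume models selected by
the HH/VV power balance (the +/-2 dB co-pol ratio branches of the original
four-component formulation); the residual is split between surface and
double-bounce by the sign of the dominant-scattering criterion.  Negative
intermediate powers are clipped and the total renormalised so the span
identity always holds (count available via logging).

Fused characteristics are arithmetic combinations of the linear powers:
Dbl/Odd, Vol/Odd, Dbl x Vol and Dbl x Vol / Odd.  For multi-acquisition
sources the base powers are temporally averaged first and the fused features
recomputed from the averaged powers (averaging ratios is NOT equivalent and
is available only behind a flag for sensitivity analysis).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .inventory import PlotRecord

log = logging.getLogger(__name__)

BASE_FEATURES = ["odd", "dbl", "vol", "hlx"]
FUSED_FEATURES = ["dbl_odd", "vol_odd", "dblxvol", "dblxvol_odd"]
#: the seven characteristics screened against GSV (helix excluded: building
#: scattering, uninformative over forest)
ANALYSIS_FEATURES = ["odd", "dbl", "vol"] + FUSED_FEATURES

FEATURE_LABELS = {
    "odd": "Odd",
    "dbl": "Dbl",
    "vol": "Vol",
    "hlx": "Hlx",
    "dbl_odd": "Dbl/Odd",
    "vol_odd": "Vol/Odd",
    "dblxvol": "Dbl×Vol",
    "dblxvol_odd": "Dbl×Vol/Odd",
}

HERMITIAN_ATOL = 1e-10
#: co-pol ratio branch threshold (dB) of the four-component volume model
COPOL_BRANCH_DB = 2.0


@dataclass(frozen=True)
class DecompPowers:
    """Yamaguchi four-component powers in linear units."""

    odd: float
    dbl: float
    vol: float
    hlx: float

    def __iter__(self):
        return iter((self.odd, self.dbl, self.vol, self.hlx))

    @property
    def span(self) -> float:
        return self.odd + self.dbl + self.vol + self.hlx


# ---------------------------------------------------------------------------
# Yamaguchi four-component decomposition
# ---------------------------------------------------------------------------

# unit-trace volume coherency models:
#   middle branch (|ratio| <= 2 dB): random dipole cloud, diag(2,1,1)/4
#   side branches: asymmetric dipole clouds, [[15,+/-5,0],[+/-5,7,0],[0,0,8]]/30
_TV_MID = (0.5, 0.25, 0.0)          # (tv11, tv22, tv12); tv33 = 1/4
_TV_LO = (0.5, 7.0 / 30.0, 5.0 / 30.0)   # VV/HH < -2 dB; tv33 = 4/15
_TV_HI = (0.5, 7.0 / 30.0, -5.0 / 30.0)  # VV/HH > +2 dB; tv33 = 4/15


def _check_hermitian(T: np.ndarray) -> None:
    scale = max(float(np.abs(T).max()), 1.0)
    if np.abs(T - np.swapaxes(T, -1, -2).conj()).max() > HERMITIAN_ATOL * scale:
        raise ValueError("coherency matrix is not Hermitian within tolerance")


def yamaguchi4_stack(T: np.ndarray) -> np.ndarray:
    """Vectorised four-component decomposition.

    ``T``: complex array (..., 3, 3), Hermitian.  Returns float array
    (..., 4) of (odd, dbl, vol, hlx) powers summing to trace(T).
    """
    T = np.asarray(T, dtype=complex)
    if T.shape[-2:] != (3, 3):
        raise ValueError("expected trailing shape (3, 3)")
    _check_hermitian(T)

    T11 = T[..., 0, 0].real
    T22 = T[..., 1, 1].real
    T33 = T[..., 2, 2].real
    T12 = T[..., 0, 1]
    span = T11 + T22 + T33

    Pc = 2.0 * np.abs(T[..., 1, 2].imag)
    Pc = np.minimum(Pc, span)

    # co-pol power ratio 10 log10(|Svv|^2 / |Shh|^2) from the Pauli entries
    svv = T11 + T22 - 2.0 * T12.real
    shh = T11 + T22 + 2.0 * T12.real
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio_db = 10.0 * np.log10(np.where((svv > 0) & (shh > 0), svv / shh, 1.0))
    lo = ratio_db < -COPOL_BRANCH_DB
    hi = ratio_db > COPOL_BRANCH_DB

    tv11 = np.where(lo | hi, _TV_LO[0], _TV_MID[0])
    tv22 = np.where(lo | hi, _TV_LO[1], _TV_MID[1])
    tv12 = np.where(lo, _TV_LO[2], np.where(hi, _TV_HI[2], _TV_MID[2]))
    tv33 = np.where(lo | hi, 4.0 / 15.0, 0.25)

    fv = (T33 - Pc / 2.0) / tv33
    Pv = np.clip(fv, 0.0, None)
    Pv = np.minimum(Pv, span - Pc)

    S = T11 - Pv * tv11
    D = T22 - Pv * tv22 - Pc / 2.0
    C = T12 - Pv * tv12
    C2 = np.abs(C) ** 2

    # dominant-scattering criterion: surface if T11 - T22 - T33 + Pc > 0
    surf_dom = (T11 - T22 - T33 + Pc) > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        ps_s = np.where(S > 0, S + C2 / np.where(S > 0, S, 1.0), S)
        pd_d = np.where(D > 0, D + C2 / np.where(D > 0, D, 1.0), D)
    Ps = np.where(surf_dom, ps_s, S + D - pd_d)
    Pd = np.where(surf_dom, S + D - ps_s, pd_d)

    rem = S + D  # = span - Pv - Pc when fv was not clipped
    Ps = np.where(rem <= 0, 0.0, Ps)
    Pd = np.where(rem <= 0, 0.0, Pd)
    neg_s = Ps < 0
    Pd = np.where(neg_s, np.clip(rem, 0.0, None), Pd)
    Ps = np.where(neg_s, 0.0, Ps)
    neg_d = Pd < 0
    Ps = np.where(neg_d, np.clip(rem, 0.0, None), Ps)
    Pd = np.where(neg_d, 0.0, Pd)

    powers = np.stack([Ps, Pd, Pv, Pc], axis=-1)
    total = powers.sum(axis=-1)
    # renormalise where clipping broke the span identity (degenerate inputs)
    bad = np.abs(total - span) > 1e-9 * np.maximum(span, 1.0)
    n_bad = int(np.count_nonzero(bad))
    if n_bad:
        log.warning("span identity restored by rescaling at %d pixel(s)", n_bad)
        with np.errstate(divide="ignore", invalid="ignore"):
            scale = np.where(total > 0, span / np.where(total > 0, total, 1.0), 0.0)
        powers = np.where(bad[..., None], powers * scale[..., None], powers)
    return powers


def yamaguchi4(t3: np.ndarray) -> DecompPowers:
    """Four-component decomposition of a single coherency matrix."""
    p = yamaguchi4_stack(np.asarray(t3)[None, ...])[0]
    return DecompPowers(*(float(v) for v in p))


# ---------------------------------------------------------------------------
# feature fusion
# ---------------------------------------------------------------------------

def fuse(p: DecompPowers) -> dict[str, float]:
    """Fused characteristics from one set of powers; ratios are NaN (missing)
    where the surface power is zero."""
    odd, dbl, vol = p.odd, p.dbl, p.vol
    if odd > 0:
        return {
            "dbl_odd": dbl / odd,
            "vol_odd": vol / odd,
            "dblxvol": dbl * vol,
            "dblxvol_odd": dbl * vol / odd,
        }
    return {
        "dbl_odd": float("nan"),
        "vol_odd": float("nan"),
        "dblxvol": dbl * vol,
        "dblxvol_odd": float("nan"),
    }


def fuse_table(df: pd.DataFrame) -> pd.DataFrame:
    """Append/recompute fused feature columns from base power columns."""
    out = df.copy()
    odd = out["odd"].to_numpy(dtype=float)
    dbl = out["dbl"].to_numpy(dtype=float)
    vol = out["vol"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        inv_odd = np.where(odd > 0, 1.0 / np.where(odd > 0, odd, 1.0), np.nan)
    out["dbl_odd"] = dbl * inv_odd
    out["vol_odd"] = vol * inv_odd
    out["dblxvol"] = dbl * vol
    out["dblxvol_odd"] = dbl * vol * inv_odd
    n_missing = int(np.count_nonzero(~(odd > 0)))
    if n_missing:
        log.warning("ratio features missing for %d row(s) with zero Odd power", n_missing)
    return out


# ---------------------------------------------------------------------------
# raster grid and plot extraction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Grid:
    """Affine pixel grid, pixel-centre registration: pixel (row, col) centre
    sits at (x0 + col*dx, y0 - row*dy)."""

    x0: float
    y0: float
    dx: float
    dy: float

    def rowcol(self, x: float, y: float) -> tuple[int, int]:
        col = int(np.rint((x - self.x0) / self.dx))
        row = int(np.rint((self.y0 - y) / self.dy))
        return row, col

    def to_dict(self) -> dict:
        return {"x0": self.x0, "y0": self.y0, "dx": self.dx, "dy": self.dy}


def extract_plot_value(
    raster: np.ndarray,
    grid: Grid,
    plot: PlotRecord,
    window: int = 7,
    max_masked_frac: float = 0.5,
) -> float:
    """Window mean of ``raster`` centred on the pixel containing the plot.

    Masked pixels are NaN and ignored.  Returns NaN (plot unusable) when the
    shadow flag is set or more than ``max_masked_frac`` of the window is
    masked.  Raises if the centre is outside the raster or the window is even.
    """
    if window % 2 == 0 or window < 1:
        raise ValueError("window must be a positive odd integer")
    row, col = grid.rowcol(plot.x, plot.y)
    H, W = raster.shape
    if not (0 <= row < H and 0 <= col < W):
        raise ValueError(f"plot {plot.id} centre falls outside the raster")
    if plot.shadow_flag:
        return float("nan")
    h = window // 2
    block = raster[max(0, row - h): row + h + 1, max(0, col - h): col + h + 1]
    n_total = window * window
    vals = block[np.isfinite(block)]
    if n_total - vals.size > max_masked_frac * n_total:
        return float("nan")
    if vals.size == 0:
        return float("nan")
    return float(vals.mean())


def extract_feature_table(
    stack: np.ndarray,
    grid: Grid,
    plots: Sequence[PlotRecord],
    source: str,
    window: int = 7,
) -> pd.DataFrame:
    """Plot-level FeatureTable from a 4-band (odd, dbl, vol, hlx) power stack."""
    rows = []
    for p in plots:
        rec: dict[str, object] = {"plot_id": p.id, "source": source, "gsv": p.gsv}
        for b, name in enumerate(BASE_FEATURES):
            rec[name] = extract_plot_value(stack[b], grid, p, window=window)
        rows.append(rec)
    return fuse_table(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# temporal averaging
# ---------------------------------------------------------------------------

def temporal_average(
    tables: Mapping[str, pd.DataFrame],
    combination: Sequence[str],
    fuse_after: bool = True,
) -> pd.DataFrame:
    """Average base powers over a combination of acquisitions, per plot, then
    recompute the fused features from the averaged powers.

    ``fuse_after=False`` instead averages the already-fused ratio features
    (sensitivity-analysis variant; not the reference behaviour).
    """
    if len(combination) < 2:
        raise ValueError("a temporal combination needs at least 2 acquisitions")
    missing = [c for c in combination if c not in tables]
    if missing:
        raise ValueError(f"unknown acquisition label(s): {missing}")
    frames = [tables[c] for c in combination]
    ids0 = frames[0]["plot_id"].tolist()
    for c, f in zip(combination, frames):
        if f["plot_id"].tolist() != ids0:
            raise ValueError(f"plot set of acquisition {c!r} does not match")

    label = ",".join(combination)
    out = frames[0][[c for c in ("plot_id", "gsv") if c in frames[0].columns]].copy()
    for col in BASE_FEATURES:
        out[col] = np.mean([f[col].to_numpy(dtype=float) for f in frames], axis=0)
    if fuse_after:
        out = fuse_table(out)
    else:
        fused = [fuse_table(f) for f in frames]
        for col in FUSED_FEATURES:
            out[col] = np.mean([f[col].to_numpy(dtype=float) for f in fused], axis=0)
    out["source"] = label
    return out


# ---------------------------------------------------------------------------
# raster file I/O (multi-band TIFF + JSON grid sidecar; binary T3 container)
# ---------------------------------------------------------------------------

def write_power_stack(path, stack: np.ndarray, grid: Grid) -> None:
    """4-band power stack as TIFF (band order odd, dbl, vol, hlx) with a JSON
    sidecar <path>.grid.json carrying the affine grid."""
    import tifffile

    tifffile.imwrite(
        str(path), np.asarray(stack, dtype=np.float32), photometric="minisblack"
    )
    with open(f"{path}.grid.json", "w") as fh:
        json.dump(grid.to_dict(), fh)


def read_power_stack(path) -> tuple[np.ndarray, Grid]:
    import tifffile

    stack = np.asarray(tifffile.imread(str(path)), dtype=float)
    with open(f"{path}.grid.json") as fh:
        grid = Grid(**json.load(fh))
    return stack, grid


def write_t3_stack(path, T: np.ndarray) -> None:
    """T3 stack as a .npy of 9 real planes per pixel:
    [T11, T22, T33, Re T12, Im T12, Re T13, Im T13, Re T23, Im T23]."""
    T = np.asarray(T, dtype=complex)
    planes = np.stack(
        [
            T[..., 0, 0].real, T[..., 1, 1].real, T[..., 2, 2].real,
            T[..., 0, 1].real, T[..., 0, 1].imag,
            T[..., 0, 2].real, T[..., 0, 2].imag,
            T[..., 1, 2].real, T[..., 1, 2].imag,
        ],
        axis=0,
    ).astype(np.float32)
    np.save(str(path), planes)


def read_t3_stack(path) -> np.ndarray:
    p = np.load(str(path)).astype(float)
    shape = p.shape[1:]
    T = np.zeros(shape + (3, 3), dtype=complex)
    T[..., 0, 0] = p[0]
    T[..., 1, 1] = p[1]
    T[..., 2, 2] = p[2]
    T[..., 0, 1] = p[3] + 1j * p[4]
    T[..., 1, 0] = p[3] - 1j * p[4]
    T[..., 0, 2] = p[5] + 1j * p[6]
    T[..., 2, 0] = p[5] - 1j * p[6]
    T[..., 1, 2] = p[7] + 1j * p[8]
    T[..., 2, 1] = p[7] - 1j * p[8]
    return T
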