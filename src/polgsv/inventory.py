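"""Field-inventory computations: tree stem volume and plot growing stock volume.

A ground plot is a square of side 20 or 30 m in which every tree with DBH
(diameter at breast height) of at least 5 cm is measured for DBH (cm) and
height (m).  The stem volume of a single tree is

    v = g * (H + 3) * f,      g = pi * (DBH / 200)^2   [m^2]

where ``g`` is the breast-height cross-section area assuming a circular stem,
``H`` the tree height in metres, and ``f`` a dimensionless trunk taper
coefficient that depends on DBH and height (species-specific tables exist for
Chinese fir; a constant-``f`` synthetic default is provided here).  Plot GSV is
the sum of tree stem volumes scaled to a hectare:

    GSV = sum_i v_i / (side^2 / 10000)   [m^3/ha]
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import pandas as pd

MIN_DBH_CM = 5.0


class SmallTreeError(ValueError):
    """Raised when a tree below the 5 cm DBH measurement threshold is passed."""


@dataclass(frozen=True)
class TreeRecord:
    """One measured tree: DBH in cm (>= 5) and height in m (> 0)."""

    dbh: float
    height: float

    def __post_init__(self) -> None:
        if self.dbh < MIN_DBH_CM:
            raise SmallTreeError(
                f"tree DBH {self.dbh:.2f} cm below the {MIN_DBH_CM:.0f} cm "
                "measurement threshold"
            )
        if not self.height > 0:
            raise ValueError(f"tree height must be positive, got {self.height}")


@dataclass
class PlotRecord:
    """A square inventory plot with its tree list.

    ``gsv`` holds the plot growing stock volume in m^3/ha once computed (or the
    generator's true value for synthetic plots).  ``shadow_flag`` marks plots in
    radar layover/shadow that must be excluded from every analysis table.
    """

    id: str
    x: float
    y: float
    side: float
    trees: list[TreeRecord] = field(default_factory=list)
    shadow_flag: bool = False
    gsv: float | None = None

    def __post_init__(self) -> None:
        if not self.side > 0:
            raise ValueError(f"plot side must be positive, got {self.side}")
        if self.gsv is not None and self.gsv < 0:
            raise ValueError(f"plot GSV must be non-negative, got {self.gsv}")

    @property
    def area_ha(self) -> float:
        return self.side**2 / 10_000.0


class TaperModel:
    """Trunk taper coefficient f(dbh, height), 0 < f <= 1.

    Wraps either a callable or a lookup table (DataFrame with columns
    ``dbh_min, dbh_max, height_min, height_max, f``; half-open bins).  The
    constant default is a synthetic stand-in for the species-specific taper
    tables used in operational inventory.
    """

    def __init__(self, fn: Callable[[float, float], float]):
        self._fn = fn

    def __call__(self, dbh: float, height: float) -> float:
        f = float(self._fn(dbh, height))
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"taper coefficient {f} outside (0, 1] at dbh={dbh}, h={height}")
        return f

    @classmethod
    def constant(cls, f: float = 0.45) -> "TaperModel":
        """Constant-f taper (synthetic default; real tables vary with size)."""
        if not 0.0 < f <= 1.0:
            raise ValueError(f"constant taper must lie in (0, 1], got {f}")
        return cls(lambda dbh, height: f)

    @classmethod
    def from_table(cls, table: pd.DataFrame) -> "TaperModel":
        required = {"dbh_min", "dbh_max", "height_min", "height_max", "f"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"taper table missing columns: {sorted(missing)}")
        rows = table.to_dict("records")

        def lookup(dbh: float, height: float) -> float:
            for r in rows:
                if r["dbh_min"] <= dbh < r["dbh_max"] and r["height_min"] <= height < r["height_max"]:
                    return float(r["f"])
            raise ValueError(f"taper table has no bin for dbh={dbh}, height={height}")

        return cls(lookup)


def cross_section_area(dbh_cm: float) -> float:
    """Breast-height cross-section area in m^2 for a circular stem."""
    return math.pi * (dbh_cm / 200.0) ** 2


def tree_stem_volume(tree: TreeRecord, taper: TaperModel) -> float:
    """Stem volume of one tree in m^3: g * (H + 3) * f."""
    g = cross_section_area(tree.dbh)
    f = taper(tree.dbh, tree.height)
    return g * (tree.height + 3.0) * f


def plot_gsv(plot: PlotRecord, taper: TaperModel) -> float:
    """Plot growing stock volume in m^3/ha (0 for an empty tree list)."""
    total = sum(tree_stem_volume(t, taper) for t in plot.trees)
    return total / plot.area_ha


def filter_measurable(
    dbh_height_pairs: Iterable[tuple[float, float]],
) -> tuple[list[TreeRecord], int]:
    """Build TreeRecords, dropping sub-threshold trees.

    Returns (records, n_excluded).  Exclusion is flagged via the count rather
    than erroring the whole plot.
    """
    records: list[TreeRecord] = []
    excluded = 0
    for dbh, height in dbh_height_pairs:
        if dbh < MIN_DBH_CM:
            excluded += 1
            continue
        records.append(TreeRecord(dbh=dbh, height=height))
    return records, excluded


# ---------------------------------------------------------------------------
# CSV interfaces
# ---------------------------------------------------------------------------

def plots_to_frames(plots: Sequence[PlotRecord]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Serialize plots to (plots, trees) DataFrames matching the CSV schema."""
    plot_rows = [
        {
            "plot_id": p.id,
            "x": p.x,
            "y": p.y,
            "side_m": p.side,
            "shadow_flag": int(p.shadow_flag),
            "gsv_m3ha": p.gsv,
        }
        for p in plots
    ]
    tree_rows = [
        {"plot_id": p.id, "dbh_cm": t.dbh, "height_m": t.height}
        for p in plots
        for t in p.trees
    ]
    return pd.DataFrame(plot_rows), pd.DataFrame(tree_rows)


def plots_from_frames(plots_df: pd.DataFrame, trees_df: pd.DataFrame) -> list[PlotRecord]:
    """Inverse of :func:`plots_to_frames`."""
    by_plot: dict[str, list[TreeRecord]] = {}
    if len(trees_df):
        for plot_id, grp in trees_df.groupby("plot_id", sort=False):
            by_plot[str(plot_id)] = [
                TreeRecord(dbh=row.dbh_cm, height=row.height_m)
                for row in grp.itertuples()
            ]
    plots = []
    for row in plots_df.itertuples():
        gsv = getattr(row, "gsv_m3ha", None)
        plots.append(
            PlotRecord(
                id=str(row.plot_id),
                x=float(row.x),
                y=float(row.y),
                side=float(row.side_m),
                trees=by_plot.get(str(row.plot_id), []),
                shadow_flag=bool(row.shadow_flag),
                gsv=None if gsv is None or pd.isna(gsv) else float(gsv),
            )
        )
    return plots


def write_plot_csvs(plots: Sequence[PlotRecord], plots_path, trees_path) -> None:
    plots_df, trees_df = plots_to_frames(plots)
    plots_df.to_csv(plots_path, index=False)
    trees_df.to_csv(trees_path, index=False)


def read_plot_csvs(plots_path, trees_path) -> list[PlotRecord]:
    return plots_from_frames(pd.read_csv(plots_path), pd.read_csv(trees_path))
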