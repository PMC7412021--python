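import numpy as np
import pandas as pd
import pytest

import polgsv as pg
from polgsv.inventory import PlotRecord
from polgsv.polarimetry import (
    Grid,
    extract_plot_value,
    fuse,
    fuse_table,
    read_power_stack,
    read_t3_stack,
    temporal_average,
    write_power_stack,
    write_t3_stack,
    yamaguchi4,
    yamaguchi4_stack,
)

from conftest import random_psd_t3


class TestYamaguchi4:
    @pytest.mark.parametrize(
        "diag,expected",
        [
            ((1, 0, 0), (1, 0, 0, 0)),      # pure surface scatterer
            ((0, 1, 0), (0, 1, 0, 0)),      # pure dihedral
            ((0.5, 0.25, 0.25), (0, 0, 1, 0)),  # random-dipole volume
        ],
    )
    def test_canonical_scatterers(self, diag, expected):
        p = yamaguchi4(np.diag(diag).astype(complex))
        assert tuple(p) == pytest.approx(expected, abs=1e-12)

    def test_helix_power_from_imag_t23(self):
        T = np.array(
            [[0.2, 0, 0], [0, 0.55, 0.05j], [0, -0.05j, 0.35]], dtype=complex
        )
        p = yamaguchi4(T)
        assert p.hlx == pytest.approx(0.1)
        assert p.span == pytest.approx(np.trace(T).real)

    def test_non_hermitian_rejected(self):
        T = np.array([[1, 0.5, 0], [0, 1, 0], [0, 0, 1]], dtype=complex)
        with pytest.raises(ValueError, match="Hermitian"):
            yamaguchi4(T)

    def test_power_sum_conservation_on_random_psd(self, rng):
        T = random_psd_t3(rng, 10_000)
        p = yamaguchi4_stack(T)
        assert (p >= 0).all()
        np.testing.assert_allclose(
            p.sum(axis=-1), np.trace(T, axis1=-2, axis2=-1).real,
            rtol=1e-8, atol=1e-8,
        )

    def test_scaling_invariance(self, rng):
        T = random_psd_t3(rng, 200)
        c = 3.7
        np.testing.assert_allclose(
            yamaguchi4_stack(c * T), c * yamaguchi4_stack(T), rtol=1e-10
        )


class TestFuse:
    def test_arithmetic_example(self):
        f = fuse(pg.DecompPowers(odd=2, dbl=4, vol=1, hlx=0))
        assert f == {"dbl_odd": 2.0, "vol_odd": 0.5, "dblxvol": 4.0, "dblxvol_odd": 2.0}

    def test_zero_odd_flags_ratios_missing(self):
        f = fuse(pg.DecompPowers(odd=0, dbl=4, vol=1, hlx=0))
        assert np.isnan(f["dbl_odd"]) and np.isnan(f["vol_odd"]) and np.isnan(f["dblxvol_odd"])
        assert f["dblxvol"] == 4.0

    def test_homogeneity_under_power_scaling(self):
        p = pg.DecompPowers(odd=2, dbl=4, vol=1, hlx=0.1)
        c = 5.0
        pc = pg.DecompPowers(odd=2 * c, dbl=4 * c, vol=1 * c, hlx=0.1 * c)
        f, fc = fuse(p), fuse(pc)
        assert fc["dbl_odd"] == pytest.approx(f["dbl_odd"])
        assert fc["vol_odd"] == pytest.approx(f["vol_odd"])
        assert fc["dblxvol"] == pytest.approx(c**2 * f["dblxvol"])

    def test_fuse_table_matches_scalar_fuse(self, rng):
        df = pd.DataFrame(rng.uniform(0.1, 2, size=(20, 4)),
                          columns=["odd", "dbl", "vol", "hlx"])
        out = fuse_table(df)
        for i in range(20):
            scalar = fuse(pg.DecompPowers(*df.iloc[i]))
            for k, v in scalar.items():
                assert out[k].iloc[i] == pytest.approx(v)


def _plot(x, y, shadow=False):
    return PlotRecord("P1", x, y, 30.0, shadow_flag=shadow)


class TestExtractPlotValue:
    grid = Grid(x0=0.0, y0=0.0, dx=10.0, dy=10.0)

    def test_constant_raster(self):
        raster = np.full((21, 21), 3.5)
        assert extract_plot_value(raster, self.grid, _plot(100, -100)) == 3.5

    def test_window_mean_equals_brute_force(self, rng):
        raster = rng.uniform(0, 1, size=(31, 41))
        plot = _plot(200, -150)  # pixel (15, 20)
        v = extract_plot_value(raster, self.grid, plot, window=7)
        assert v == pytest.approx(raster[12:19, 17:24].mean(), rel=1e-12)

    def test_masked_pixels_ignored_until_half(self):
        raster = np.full((21, 21), 2.0)
        raster[7:14, 7:12] = np.nan  # 35 of 49 masked -> unusable
        assert np.isnan(extract_plot_value(raster, self.grid, _plot(100, -100)))
        raster[7:14, 7:12] = 2.0
        raster[7:14, 7:10] = np.nan  # 21 of 49 masked -> still usable
        assert extract_plot_value(raster, self.grid, _plot(100, -100)) == 2.0

    def test_shadow_plot_is_unusable(self):
        raster = np.ones((21, 21))
        assert np.isnan(
            extract_plot_value(raster, self.grid, _plot(100, -100, shadow=True))
        )

    def test_out_of_bounds_names_the_plot(self):
        with pytest.raises(ValueError, match="P1"):
            extract_plot_value(np.ones((5, 5)), self.grid, _plot(1000, -1000))

    def test_even_window_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            extract_plot_value(np.ones((9, 9)), self.grid, _plot(40, -40), window=6)


class TestTemporalAverage:
    @staticmethod
    def _table(odd, dbl, vol=1.0, hlx=0.01):
        return fuse_table(pd.DataFrame({
            "plot_id": ["a", "b"], "gsv": [100.0, 200.0],
            "odd": odd, "dbl": dbl, "vol": [vol] * 2, "hlx": [hlx] * 2,
        }))

    def test_idempotent_on_identical_acquisitions(self):
        t = self._table([1.0, 2.0], [0.5, 0.7])
        out = temporal_average({"1": t, "2": t.copy()}, ["1", "2"])
        for col in ["odd", "dbl", "vol", "hlx", "dbl_odd", "dblxvol_odd"]:
            np.testing.assert_allclose(out[col], t[col])
        assert (out["source"] == "1,2").all()

    def test_base_powers_averaged(self):
        t1 = self._table([1.0, 1.0], [1.0, 1.0])
        t2 = self._table([1.0, 1.0], [3.0, 3.0])
        out = temporal_average({"1": t1, "2": t2}, ["1", "2"])
        np.testing.assert_allclose(out["dbl"], [2.0, 2.0])

    def test_average_then_fuse_order(self):
        """odd = (1, 4), dbl = (4, 1) across two acquisitions: recomputing the
        ratio from averaged powers gives 1, averaging ratios gives 2.125."""
        t1 = self._table([1.0, 1.0], [4.0, 4.0])
        t2 = self._table([4.0, 4.0], [1.0, 1.0])
        tabs = {"1": t1, "2": t2}
        after = temporal_average(tabs, ["1", "2"])
        np.testing.assert_allclose(after["dbl_odd"], [1.0, 1.0])
        before = temporal_average(tabs, ["1", "2"], fuse_after=False)
        np.testing.assert_allclose(before["dbl_odd"], [2.125, 2.125])

    def test_mismatched_plot_sets_rejected(self):
        t1 = self._table([1.0, 2.0], [1.0, 2.0])
        t2 = t1.copy()
        t2["plot_id"] = ["a", "c"]
        with pytest.raises(ValueError, match="plot set"):
            temporal_average({"1": t1, "2": t2}, ["1", "2"])

    def test_single_acquisition_combination_rejected(self):
        t = self._table([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(ValueError, match="at least 2"):
            temporal_average({"1": t}, ["1"])

    def test_variance_reduction_scales_as_one_over_k(self):
        """Averaging k i.i.d. noisy replicates shrinks per-plot power variance
        by about 1/k."""
        rng = np.random.default_rng(3)
        k = 4
        n_rep = 400
        single_var, avg_var = [], []
        for _ in range(n_rep):
            reps = [
                self._table(np.exp(rng.normal(0, 0.3, 2)).tolist(),
                            np.exp(rng.normal(0, 0.3, 2)).tolist())
                for _ in range(k)
            ]
            tabs = {str(i): r for i, r in enumerate(reps)}
            out = temporal_average(tabs, list(tabs))
            single_var.append(reps[0]["dbl"].iloc[0])
            avg_var.append(out["dbl"].iloc[0])
        ratio = np.var(avg_var) / np.var(single_var)
        assert ratio == pytest.approx(1 / k, rel=0.35)


def test_power_stack_io_round_trip(tmp_path, rng):
    stack = rng.uniform(0, 1, size=(4, 14, 14)).astype(np.float32)
    grid = Grid(1.0, 2.0, 10.0, 10.0)
    path = tmp_path / "stack.tif"
    write_power_stack(path, stack, grid)
    back, grid2 = read_power_stack(path)
    np.testing.assert_allclose(back, stack)
    assert grid2 == grid


def test_t3_container_round_trip(tmp_path, rng):
    T = random_psd_t3(rng, 36).reshape(6, 6, 3, 3)
    path = tmp_path / "t3.npy"
    write_t3_stack(path, T)
    back = read_t3_stack(path)
    np.testing.assert_allclose(back, T, rtol=1e-6, atol=1e-5)
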