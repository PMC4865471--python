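"""Target derivation: densities, regression, random draws, series designs."""
import math

import numpy as np
import pandas as pd
import pytest

from landgen import (
    ReferencePatchTable,
    draw_top_patches,
    fit_loglog_area_perim,
    np_te_from_densities,
    parse_targets_file,
    recreation_targets,
    series1_targets,
    series2_targets,
    write_targets_file,
)
from landgen.targets import series1_patch_areas


def square_table(n=30, seed=0):
    """Patch table of perfect squares: PERIM = 4 sqrt(AREA) exactly."""
    rng = np.random.default_rng(seed)
    sides = rng.integers(1, 40, size=n)
    return ReferencePatchTable(
        pd.DataFrame(
            {
                "class_code": 1,
                "area": (sides**2).astype(float),
                "perim": (4 * sides).astype(float),
            }
        )
    )


class TestDensities:
    def test_np_from_pd(self):
        assert np_te_from_densities(0.5, 0.0, 1000)[0] == 5

    def test_te_from_ed(self):
        assert np_te_from_densities(0.0, 12.0, 250)[1] == 30.0

    def test_np_floored_at_one_with_warning(self):
        with pytest.warns(UserWarning, match="flooring NP at 1"):
            n, _ = np_te_from_densities(0.001, 0.0, 100)
        assert n == 1

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            np_te_from_densities(-1.0, 0.0, 100)


class TestLogLogRegression:
    def test_perfect_squares_recover_half_slope(self):
        fit = fit_loglog_area_perim(square_table(), 1)
        assert fit.slope == pytest.approx(0.5, abs=1e-9)
        assert fit.intercept == pytest.approx(math.log(4.0), abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert fit.predict_perimeter(100.0) == pytest.approx(40.0)

    def test_noiseless_synthetic_recovers_parameters(self):
        a, b = 1.1, 0.62
        areas = np.linspace(5, 500, 40)
        table = ReferencePatchTable(
            pd.DataFrame(
                {
                    "class_code": 2,
                    "area": areas,
                    "perim": np.exp(a) * areas**b,
                }
            )
        )
        fit = fit_loglog_area_perim(table, 2)
        assert fit.intercept == pytest.approx(a, abs=1e-9)
        assert fit.slope == pytest.approx(b, abs=1e-9)

    def test_noisy_slope_within_three_se(self):
        rng = np.random.default_rng(7)
        a, b, n = 0.9, 0.55, 200
        areas = rng.uniform(10, 1000, size=n)
        perims = np.exp(a + b * np.log(areas) + rng.normal(0, 0.05, size=n))
        table = ReferencePatchTable(
            pd.DataFrame({"class_code": 1, "area": areas, "perim": perims})
        )
        fit = fit_loglog_area_perim(table, 1)
        assert abs(fit.slope - b) < 3 * fit.se_slope

    def test_too_few_patches_rejected(self):
        table = ReferencePatchTable(
            pd.DataFrame({"class_code": [1, 1], "area": [4, 9], "perim": [8, 12]})
        )
        with pytest.raises(ValueError, match=">= 3"):
            fit_loglog_area_perim(table, 1)


class TestDrawTopPatches:
    def test_exhaustive_draw_returns_overall_largest(self):
        table = square_table(n=20, seed=3)
        picks = draw_top_patches(table, 1, n_patches=20, k=3, seed=5)
        want = sorted(table.frame["area"], reverse=True)[:3]
        assert [a for a, _ in picks] == want

    def test_k1_single_draw(self):
        table = ReferencePatchTable(
            pd.DataFrame(
                {"class_code": 1, "area": [100.0] * 6, "perim": [40.0] * 6}
            )
        )
        fit = fit_loglog_area_perim(square_table(), 1)
        picks = draw_top_patches(table, 1, n_patches=1, k=1, seed=2, fit=fit)
        assert len(picks) == 1

    def test_seeded_and_deterministic(self):
        table = square_table(n=15, seed=2)
        one = draw_top_patches(table, 1, n_patches=5, k=3, seed=11)
        two = draw_top_patches(table, 1, n_patches=5, k=3, seed=11)
        assert one == two

    def test_uniform_selection_over_equal_patches(self):
        # one of 5 equal-area patches drawn per seed: each within 3 sigma
        table = ReferencePatchTable(
            pd.DataFrame(
                {
                    "class_code": 1,
                    "area": [100.0] * 5,
                    "perim": [40.0, 41.0, 42.0, 43.0, 44.0],
                }
            )
        )
        fit = fit_loglog_area_perim(square_table(), 1)
        rng = np.random.default_rng(0)
        counts = np.zeros(5)
        n = 4000
        for _ in range(n):
            sub = table.frame.sample(1, random_state=rng.integers(2**31))
            counts[sub.index[0]] += 1
        p = 1 / 5
        sigma = math.sqrt(n * p * (1 - p))
        assert np.all(np.abs(counts - n * p) < 3.5 * sigma)

    def test_area_floor_filters_small_draws(self):
        frame = pd.DataFrame(
            {
                "class_code": 1,
                "area": [1.0, 1.0, 1.0, 1000.0],
                "perim": [4.0, 4.0, 4.0, 130.0],
            }
        )
        table = ReferencePatchTable(frame)
        fit = fit_loglog_area_perim(square_table(), 1)
        picks = draw_top_patches(table, 1, n_patches=4, k=3, seed=0, fit=fit)
        assert [a for a, _ in picks] == [1000.0]  # the 2% floor drops the rest


class TestSeries1:
    def test_printed_values_for_nine_patches_level_four(self):
        obj = series1_targets(9, 4)
        te = next(t for t in obj.targets if t.metric == "TE")
        assert te.value == 267.0 and te.bound == "max"
        areas = sorted(
            (t.value for t in obj.targets if t.metric == "AREA"), reverse=True
        )
        assert areas == [89.0] + [1.0] * 8

    def test_level_one_equal_areas(self):
        obj = series1_targets(9, 1)
        areas = [t.value for t in obj.targets if t.metric == "AREA"]
        assert areas == [11.0] * 9

    @pytest.mark.parametrize("n", [3, 9, 15, 21])
    @pytest.mark.parametrize("level", [1, 2, 3, 4])
    def test_pland_always_35_65(self, n, level):
        obj = series1_targets(n, level)
        pland = {t.class_code: t.value for t in obj.targets if t.metric == "PLAND"}
        assert pland == {1: 35.0, 2: 65.0}

    def test_area_tolerance_one_point(self):
        obj = series1_targets(15, 2)
        assert all(
            t.tolerance == 1.0 for t in obj.targets if t.metric == "AREA"
        )

    def test_patch_areas_sum_to_class_area(self):
        for n in (3, 9, 15, 21):
            for level in (1, 2, 3, 4):
                areas = series1_patch_areas(n, level, 875)
                assert sum(areas) == 875
                # the first (largest-target) patch absorbs the rounding
                # residual, so it can undercut the others by one cell
                assert areas[0] >= max(areas) - 1

    def test_sixteen_distinct_configurations(self):
        texts = {
            write_targets_file(series1_targets(n, lvl))
            for n in (3, 9, 15, 21)
            for lvl in (1, 2, 3, 4)
        }
        assert len(texts) == 16

    def test_out_of_domain_rejected(self):
        with pytest.raises(ValueError):
            series1_targets(4, 1)
        with pytest.raises(ValueError):
            series1_targets(9, 5)


class TestSeries2:
    @pytest.mark.parametrize(
        "level,perim", [(1, 130.0), (2, 462.0), (3, 795.0), (4, 1127.0)]
    )
    def test_perimeter_levels(self, level, perim):
        obj = series2_targets(level, 15)
        t = next(t for t in obj.targets if t.metric == "PERIM")
        assert t.value == perim and t.bound == "max"

    def test_class2_te_bound_800(self):
        obj = series2_targets(1, 35)
        t = next(t for t in obj.targets if t.metric == "TE")
        assert t.value == 800.0 and t.class_code == 2

    def test_econ_target_and_contrast(self):
        obj = series2_targets(2, 55)
        t = next(t for t in obj.targets if t.metric == "ECON")
        assert t.value == 55.0
        assert obj.contrast == (1, 2)

    def test_np_targets(self):
        obj = series2_targets(3, 75)
        np_by_class = {t.class_code: t.value for t in obj.targets if t.metric == "NP"}
        assert np_by_class == {1: 1.0, 2: 10.0}

    def test_sixteen_distinct_configurations(self):
        texts = {
            write_targets_file(series2_targets(lvl, e))
            for lvl in (1, 2, 3, 4)
            for e in (15, 35, 55, 75)
        }
        assert len(texts) == 16

    def test_builders_round_trip_through_grammar(self):
        for builder in (lambda: series1_targets(9, 4), lambda: series2_targets(2, 35)):
            obj = builder()
            back = parse_targets_file(write_targets_file(obj))
            assert back.targets == obj.targets
            assert back.grid == obj.grid
            assert back.contrast == obj.contrast


class TestRecreationTargets:
    def test_structure_of_derived_objectives(self):
        table = square_table(n=40, seed=9)
        obj = recreation_targets(
            pland={1: 100.0},
            pd_values={1: 0.5},
            ed_values={1: 40.0},
            area=2000.0,
            table=table,
            seed=3,
        )
        metrics = [t.metric for t in obj.targets]
        assert metrics.count("PLAND") == 1
        assert metrics.count("NP") == 1
        assert metrics.count("TE") == 1
        assert metrics.count("AREA") == metrics.count("PERIM") == 3
        np_t = next(t for t in obj.targets if t.metric == "NP")
        assert np_t.value == 10.0  # 0.5 per 100 over 2000 units
        assert parse_targets_file(write_targets_file(obj)).targets == obj.targets
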