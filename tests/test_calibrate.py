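import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from paleodemo import (SpeciesCalibration, calibrate_trajectory,
                       pool_replicates, restrict_window, scale_time_to_years,
                       theta_to_Ne)
from paleodemo.registry import (DEFAULT_MUTATION_RATES, GENERATION_TIMES_YEARS,
                                calibration_for, load_study_inventory,
                                marker_class_for)


def make_replicate(medians, sds, ns):
    k = len(medians)
    return pd.DataFrame({
        "bin_start": np.arange(k, dtype=float),
        "bin_stop": np.arange(1, k + 1, dtype=float),
        "median": medians, "sd": sds, "n": ns,
    })


class TestPoolReplicates:
    def test_equal_weights_reduce_to_means(self):
        reps = [make_replicate([1.0], [0.2], [50]),
                make_replicate([2.0], [0.2], [50]),
                make_replicate([3.0], [0.2], [50])]
        out = pool_replicates(reps)
        assert out["m_p"].iloc[0] == pytest.approx(2.0)
        assert out["sd_p"].iloc[0] == pytest.approx(0.2, rel=0.02)

    def test_weighted_median_hand_arithmetic(self):
        reps = [make_replicate([1.0], [0.1], [100]),
                make_replicate([2.0], [0.1], [200]),
                make_replicate([3.0], [0.1], [100])]
        out = pool_replicates(reps)
        # (100*1 + 200*2 + 100*3) / 400 = 2.0
        assert out["m_p"].iloc[0] == pytest.approx(2.0)

    def test_zero_sds_give_zero_width_ci(self):
        reps = [make_replicate([1.5], [0.0], [10]),
                make_replicate([1.5], [0.0], [10])]
        out = pool_replicates(reps)
        assert out["sd_p"].iloc[0] == 0.0
        assert out["ci_lo"].iloc[0] == out["ci_hi"].iloc[0] == pytest.approx(1.5)

    def test_identical_replicates_unchanged(self):
        rep = make_replicate([1.0, 2.0], [0.3, 0.4], [20, 30])
        out = pool_replicates([rep.copy(), rep.copy(), rep.copy()])
        assert np.allclose(out["m_p"], rep["median"])
        assert np.allclose(out["sd_p"], rep["sd"], rtol=0.05)

    def test_pooled_sd_formula(self):
        reps = [make_replicate([1.0], [0.2], [10]),
                make_replicate([2.0], [0.4], [20])]
        out = pool_replicates(reps)
        expected = np.sqrt((9 * 0.04 + 19 * 0.16) / (30 - 2))
        assert out["sd_p"].iloc[0] == pytest.approx(expected)
        assert out["ci_hi"].iloc[0] - out["m_p"].iloc[0] == pytest.approx(
            1.96 * expected / np.sqrt(30))

    def test_empty_bins_emitted_as_missing(self):
        reps = [make_replicate([1.0, np.nan], [0.1, np.nan], [10, 0]),
                make_replicate([2.0, np.nan], [0.1, np.nan], [10, 0])]
        out = pool_replicates(reps)
        assert np.isnan(out["m_p"].iloc[1])
        assert out["n_total"].iloc[1] == 0

    def test_mismatched_grids_hard_error(self):
        a = make_replicate([1.0], [0.1], [10])
        b = make_replicate([1.0], [0.1], [10])
        b["bin_start"] += 0.5
        with pytest.raises(ValueError, match="grids"):
            pool_replicates([a, b])

    def test_needs_two_replicates(self):
        with pytest.raises(ValueError, match="2 replicates"):
            pool_replicates([make_replicate([1.0], [0.1], [10])])

    def test_ci_denominator_option(self):
        reps = [make_replicate([1.0], [0.5], [50]),
                make_replicate([2.0], [0.5], [50])]
        a = pool_replicates(reps, ci_denominator="sqrt_total_n")
        b = pool_replicates(reps, ci_denominator="total_n")
        assert (a["ci_hi"].iloc[0] - a["m_p"].iloc[0]) == pytest.approx(
            (b["ci_hi"].iloc[0] - b["m_p"].iloc[0]) * np.sqrt(100))

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.tuples(st.floats(0.1, 10), st.floats(0, 1),
                              st.integers(1, 500)),
                    min_size=2, max_size=5))
    def test_pooled_median_is_convex_combination(self, spec):
        reps = [make_replicate([m], [s], [n]) for (m, s, n) in spec]
        out = pool_replicates(reps)
        ms = [m for (m, _, _) in spec]
        assert min(ms) - 1e-9 <= out["m_p"].iloc[0] <= max(ms) + 1e-9


class TestCalibrations:
    def test_ne_from_theta(self):
        calib = SpeciesCalibration("control_region", 21.2,
                                   mu_per_site_per_generation=1.125e-6)
        assert theta_to_Ne(0.01, calib) == pytest.approx(0.01 / (4 * 1.125e-6))
        assert theta_to_Ne(0.01, calib) == pytest.approx(2222.2, rel=1e-4)

    def test_ne_identity_point_and_proportionality(self):
        mu = 1.125e-6
        calib = SpeciesCalibration("control_region", 21.2,
                                   mu_per_site_per_generation=mu)
        assert theta_to_Ne(4 * mu, calib) == pytest.approx(1.0)
        calib2 = SpeciesCalibration("control_region", 21.2,
                                    mu_per_site_per_generation=2 * mu)
        assert theta_to_Ne(0.01, calib2) == pytest.approx(
            theta_to_Ne(0.01, calib) / 2)

    def test_years_unit_identities(self):
        calib = SpeciesCalibration("control_region", 21.2,
                                   mu_per_site_per_generation=1.125e-6)
        # one generation's worth of substitutions -> one generation in years
        assert scale_time_to_years(1.125e-6, calib) == pytest.approx(21.2)
        assert scale_time_to_years(0.001, calib) == pytest.approx(
            0.001 / 1.125e-6 * 21.2)
        assert scale_time_to_years(0.001, calib) == pytest.approx(18_844, rel=1e-3)
        nuc = SpeciesCalibration("nuclear", 21.2, mu_per_site_per_year=1.07e-9)
        assert scale_time_to_years(1.07e-9, nuc) == pytest.approx(1.0)

    def test_monotone_scalings(self):
        calib = SpeciesCalibration("other_mtdna", 10.0,
                                   mu_per_site_per_generation=3.4e-7)
        ts = np.array([0.0, 1e-5, 1e-4, 1e-3])
        years = scale_time_to_years(ts, calib)
        assert (np.diff(years) > 0).all()


class TestRestrictWindow:
    def _traj(self, starts, stops):
        return pd.DataFrame({
            "year_start": starts, "year_stop": stops,
            "m_p": np.linspace(1, 2, len(starts)),
        })

    def test_clips_to_window(self):
        traj = self._traj(np.arange(0, 50_000, 5000.0),
                          np.arange(5000, 55_000, 5000.0))
        out = restrict_window(traj, 1, 30)
        assert out["year_start"].min() == 1000.0
        assert out["year_stop"].max() == 30_000.0

    def test_inside_window_unchanged(self):
        traj = self._traj([2000.0, 10_000.0], [10_000.0, 25_000.0])
        out = restrict_window(traj, 1, 30)
        pd.testing.assert_frame_equal(out, traj)

    def test_everything_outside_is_error(self):
        traj = self._traj([40_000.0], [50_000.0])
        with pytest.raises(ValueError, match="window"):
            restrict_window(traj, 1, 30)


class TestRegistry:
    def test_default_rates(self):
        assert DEFAULT_MUTATION_RATES["control_region"] == 1.125e-6
        assert DEFAULT_MUTATION_RATES["other_mtdna"] == 3.4e-7
        assert DEFAULT_MUTATION_RATES["nuclear"] == 1.07e-9
        assert GENERATION_TIMES_YEARS["Balaenoptera physalus"] == 32.5

    def test_marker_classes(self):
        assert marker_class_for("CR") == "control_region"
        assert marker_class_for("COI") == "other_mtdna"
        assert marker_class_for("SNPs") == "nuclear"
        with pytest.raises(ValueError):
            marker_class_for("XYZ")

    def test_calibration_for_nuclear_derives_generational_rate(self):
        calib = calibration_for("SNPs", 32.5)
        assert calib.mu_per_site_per_year == 1.07e-9
        assert calib.mu_per_site_per_generation == pytest.approx(1.07e-9 * 32.5)

    def test_inventory_loads(self):
        inv = load_study_inventory()
        assert {"species", "ocean", "group", "n"} <= set(inv.columns)
        assert len(inv) == 23


def test_calibrate_trajectory_adds_year_columns():
    pooled = pd.DataFrame({
        "bin_start": [0.0, 1e-4], "bin_stop": [1e-4, 2e-4],
        "m_p": [0.01, 0.02], "sd_p": [0.001, 0.001],
        "ci_lo": [0.009, 0.019], "ci_hi": [0.011, 0.021],
        "n_total": [10, 10],
    })
    calib = SpeciesCalibration("control_region", 21.2,
                               mu_per_site_per_generation=1.125e-6)
    out = calibrate_trajectory(pooled, calib)
    assert out["year_stop"].iloc[0] == pytest.approx(1e-4 / 1.125e-6 * 21.2)
    assert out["Ne"].iloc[0] == pytest.approx(0.01 / (4 * 1.125e-6))
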