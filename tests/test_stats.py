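import itertools
import math
from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from dielflux import (
    DielCycle,
    bin_by_depth,
    compute_flr,
    flr_exceedance_test,
    hourly_profile,
    weighted_geometric_mean,
    wilcoxon_day_night,
)
from dielflux.stats import flr_summary_by_unit


def make_cycle(sunrise, sunset, next_sunrise, lake_id="L1", index=0):
    sr, ss, nsr = map(pd.Timestamp, (sunrise, sunset, next_sunrise))
    return DielCycle(lake_id, index, sr, ss, nsr, (ss - sr) / pd.Timedelta(hours=1))


def flux_row(t_start, t_end, flux, chamber="C1", lake="L1"):
    t0, t1 = pd.Timestamp(t_start), pd.Timestamp(t_end)
    return {
        "lake_id": lake,
        "chamber_id": chamber,
        "t_start": t0,
        "t_end": t1,
        "duration_h": (t1 - t0) / pd.Timedelta(hours=1),
        "flux_umol_m2_h": flux,
        "method": "afc_endpoints",
        "qc": "",
    }


# ---------------------------------------------------------------------------
# weighted geometric mean


class TestWeightedGeometricMean:
    def test_idempotent_on_constant(self):
        assert weighted_geometric_mean([3.3, 3.3, 3.3], [1, 5, 2]) == pytest.approx(3.3)

    def test_equal_weights_closed_form(self):
        assert weighted_geometric_mean([1.0, 4.0], [1.0, 1.0]) == pytest.approx(2.0)

    def test_unequal_weights_closed_form(self):
        # weights 3:1 -> 1^(3/4) * 4^(1/4) = 4^(1/4)
        got = weighted_geometric_mean([1.0, 4.0], [3.0, 1.0])
        assert got == pytest.approx(4.0 ** 0.25, rel=1e-12)
        assert got == pytest.approx(1.4142, abs=1e-4)

    def test_empty_returns_nan(self):
        assert math.isnan(weighted_geometric_mean([], []))

    def test_nonpositive_value_rejected(self):
        with pytest.raises(ValueError):
            weighted_geometric_mean([1.0, -2.0], [1.0, 1.0])

    @settings(max_examples=100, deadline=None)
    @given(
        values=st.lists(st.floats(0.01, 1e4), min_size=1, max_size=20),
        seed=st.integers(0, 2**16),
    )
    def test_am_gm_inequality(self, values, seed):
        rng = np.random.default_rng(seed)
        weights = rng.uniform(0.1, 5.0, len(values))
        gm = weighted_geometric_mean(values, weights)
        am = np.average(values, weights=weights)
        assert gm <= am * (1 + 1e-12)


# ---------------------------------------------------------------------------
# hourly profile


class TestHourlyProfile:
    def test_constant_chamber_flat_profile(self):
        rows = []
        t = pd.Timestamp("2018-09-01 00:00")
        for i in range(48):  # two days of hourly closures
            rows.append(flux_row(t, t + pd.Timedelta(hours=1), 5.0))
            t += pd.Timedelta(hours=1)
        prof = hourly_profile(pd.DataFrame(rows), utc_offset=0.0, lake_id="L1")
        assert len(prof) == 24
        assert np.allclose(prof["gw_mean_flux"], 5.0)

    def test_two_hour_flux_weights_split_across_hours(self):
        df = pd.DataFrame([flux_row("2018-09-01 10:00", "2018-09-01 12:00", 7.0)])
        prof = hourly_profile(df, utc_offset=0.0, lake_id="L1")
        assert list(prof["hour_of_day"]) == [10, 11]
        assert np.allclose(prof["total_weight_h"], [1.0, 1.0])

    def test_utc_offset_shifts_clock_hours(self):
        df = pd.DataFrame([flux_row("2018-09-01 10:00", "2018-09-01 11:00", 7.0)])
        prof = hourly_profile(df, utc_offset=2.0, lake_id="L1")
        assert list(prof["hour_of_day"]) == [12]

    def test_nonpositive_fluxes_excluded_and_counted(self):
        df = pd.DataFrame(
            [
                flux_row("2018-09-01 10:00", "2018-09-01 11:00", 7.0),
                flux_row("2018-09-01 10:00", "2018-09-01 11:00", -1.0),
                flux_row("2018-09-01 10:00", "2018-09-01 11:00", 0.0),
            ]
        )
        prof = hourly_profile(df, utc_offset=0.0, lake_id="L1")
        assert prof.attrs["n_excluded_nonpositive"] == 2
        assert prof.loc[0, "gw_mean_flux"] == pytest.approx(7.0)

    def test_hour_without_data_is_missing_not_zero(self):
        df = pd.DataFrame([flux_row("2018-09-01 10:00", "2018-09-01 11:00", 7.0)])
        prof = hourly_profile(df, utc_offset=0.0, lake_id="L1")
        assert 3 not in set(prof["hour_of_day"])

    def test_profile_bounded_by_observed_fluxes(self):
        rng = np.random.default_rng(8)
        rows = []
        t = pd.Timestamp("2018-09-01 00:00")
        fluxes = rng.lognormal(2.0, 0.8, 100)
        for f in fluxes:
            rows.append(flux_row(t, t + pd.Timedelta(minutes=90), f))
            t += pd.Timedelta(minutes=100)
        prof = hourly_profile(pd.DataFrame(rows), utc_offset=0.0, lake_id="L1")
        assert (prof["gw_mean_flux"] >= fluxes.min() - 1e-12).all()
        assert (prof["gw_mean_flux"] <= fluxes.max() + 1e-12).all()


# ---------------------------------------------------------------------------
# FL_R


CYCLE = make_cycle("2018-09-01 06:00", "2018-09-01 18:00", "2018-09-02 06:02")


class TestComputeFlr:
    def test_constant_flux_gives_unit_ratio(self):
        rows = []
        t = pd.Timestamp("2018-09-01 06:00")
        while t < pd.Timestamp("2018-09-02 06:00"):
            rows.append(flux_row(t, t + pd.Timedelta(hours=1), 4.2))
            t += pd.Timedelta(hours=1)
        flr = compute_flr(pd.DataFrame(rows), [CYCLE])
        assert len(flr) == 1
        assert flr.loc[0, "FL_R"] == pytest.approx(1.0)

    def test_hand_weighted_means(self):
        # day: 2 for 1 h and 4 for 3 h -> F_day = (2*1 + 4*3)/4 = 3.5
        # night: 1 throughout -> FL_R = 3.5
        rows = [
            flux_row("2018-09-01 08:00", "2018-09-01 09:00", 2.0),
            flux_row("2018-09-01 10:00", "2018-09-01 13:00", 4.0),
            flux_row("2018-09-01 18:00", "2018-09-02 06:00", 1.0),
        ]
        flr = compute_flr(pd.DataFrame(rows), [CYCLE])
        assert flr.loc[0, "F_day"] == pytest.approx(3.5)
        assert flr.loc[0, "F_night"] == pytest.approx(1.0)
        assert flr.loc[0, "FL_R"] == pytest.approx(3.5)

    def test_square_wave_cycle_aligned_records_give_exact_r(self):
        # records wholly inside day (r*base) or night (base): FL_R == r exactly
        base, r = 30.0, 2.5
        rows = []
        t = pd.Timestamp("2018-09-01 06:00")
        while t < pd.Timestamp("2018-09-02 06:00"):
            end = t + pd.Timedelta(hours=1)
            if end <= CYCLE.t_sunset:
                rows.append(flux_row(t, end, base * r))
            elif t >= CYCLE.t_sunset:
                rows.append(flux_row(t, end, base))
            t = end
        flr = compute_flr(pd.DataFrame(rows), [CYCLE])
        assert flr.loc[0, "FL_R"] == pytest.approx(r, rel=1e-12)

    def test_nonpositive_night_flagged_undefined(self):
        rows = [
            flux_row("2018-09-01 08:00", "2018-09-01 12:00", 2.0),
            flux_row("2018-09-01 19:00", "2018-09-02 05:00", -0.5),
        ]
        flr = compute_flr(pd.DataFrame(rows), [CYCLE])
        assert math.isnan(flr.loc[0, "FL_R"])
        assert flr.loc[0, "flag"] == "undefined_flr_nonpositive_night"

    def test_missing_night_coverage_skipped(self):
        rows = [flux_row("2018-09-01 08:00", "2018-09-01 12:00", 2.0)]
        flr = compute_flr(pd.DataFrame(rows), [CYCLE])
        assert flr.empty

    def test_straddling_record_split_proportionally(self):
        # 17:00-19:00 at flux 6 straddles sunset: 1 h to day, 1 h to night
        rows = [
            flux_row("2018-09-01 08:00", "2018-09-01 17:00", 2.0),
            flux_row("2018-09-01 17:00", "2018-09-01 19:00", 6.0),
            flux_row("2018-09-01 19:00", "2018-09-02 06:00", 1.0),
        ]
        flr = compute_flr(pd.DataFrame(rows), [CYCLE])
        f_day = (2.0 * 9 + 6.0 * 1) / 10
        f_night = (6.0 * 1 + 1.0 * 11) / 12
        assert flr.loc[0, "F_day"] == pytest.approx(f_day)
        assert flr.loc[0, "F_night"] == pytest.approx(f_night)

    @settings(max_examples=30, deadline=None)
    @given(scale=st.floats(0.01, 100.0))
    def test_scale_invariance(self, scale):
        rows = [
            flux_row("2018-09-01 08:00", "2018-09-01 12:00", 2.0),
            flux_row("2018-09-01 13:00", "2018-09-01 16:00", 5.0),
            flux_row("2018-09-01 19:00", "2018-09-02 05:00", 1.5),
        ]
        df = pd.DataFrame(rows)
        base = compute_flr(df, [CYCLE]).loc[0, "FL_R"]
        scaled_df = df.assign(flux_umol_m2_h=df["flux_umol_m2_h"] * scale)
        scaled = compute_flr(scaled_df, [CYCLE]).loc[0, "FL_R"]
        assert scaled == pytest.approx(base, rel=1e-9)

    def test_unit_pooling_by_depth_bin(self):
        rows = [
            flux_row("2018-09-01 08:00", "2018-09-01 12:00", 2.0, chamber="A"),
            flux_row("2018-09-01 08:00", "2018-09-01 12:00", 4.0, chamber="B"),
            flux_row("2018-09-01 19:00", "2018-09-02 05:00", 1.0, chamber="A"),
            flux_row("2018-09-01 19:00", "2018-09-02 05:00", 2.0, chamber="B"),
        ]
        unit_of = {"A": "shallow", "B": "shallow"}
        flr = compute_flr(pd.DataFrame(rows), [CYCLE], unit_of=unit_of)
        assert list(flr["unit_id"]) == ["shallow"]
        assert flr.loc[0, "F_day"] == pytest.approx(3.0)
        assert flr.loc[0, "F_night"] == pytest.approx(1.5)

    def test_summary_by_unit_unweighted_mean(self):
        df = pd.DataFrame(
            {
                "lake_id": ["L1"] * 3,
                "unit_id": ["A", "A", "B"],
                "FL_R": [2.0, 4.0, 1.0],
            }
        )
        out = flr_summary_by_unit(df)
        assert out.set_index("unit_id").loc["A", "mean_flr"] == pytest.approx(3.0)


# ---------------------------------------------------------------------------
# depth bins


class TestBinByDepth:
    @pytest.mark.parametrize(
        "depth,label",
        [(0.4, "<0.5"), (0.5, "0.5-1"), (0.99, "0.5-1"), (1.0, "1-1.5"),
         (1.2, "1-1.5"), (1.5, ">1.5"), (2.0, ">1.5")],
    )
    def test_bin_assignment(self, depth, label):
        ch = SimpleNamespace(chamber_id="X", depth_m=depth)
        assert bin_by_depth([ch])["X"] == label

    def test_missing_depth_unbinned(self):
        ch = SimpleNamespace(chamber_id="X", depth_m=float("nan"))
        assert "X" not in bin_by_depth([ch])


# ---------------------------------------------------------------------------
# rank tests with enumeration oracles


def rank_sum_exact_p_greater(day, night):
    """One-sided exact rank-sum p via full enumeration of label assignments."""
    pooled = np.concatenate([day, night])
    ranks = pd.Series(pooled).rank().to_numpy()
    n_day = len(day)
    w_obs = ranks[:n_day].sum()
    count = total = 0
    for combo in itertools.combinations(range(len(pooled)), n_day):
        total += 1
        if ranks[list(combo)].sum() >= w_obs - 1e-12:
            count += 1
    return count / total


def signed_rank_exact_p_greater(x, null=1.0):
    """One-sided exact signed-rank p via enumeration of all sign patterns."""
    d = np.asarray(x, dtype=float) - null
    d = d[d != 0]
    ranks = pd.Series(np.abs(d)).rank().to_numpy()
    w_obs = ranks[d > 0].sum()
    count = total = 0
    for signs in itertools.product([0, 1], repeat=len(d)):
        total += 1
        w = ranks[np.array(signs, dtype=bool)].sum()
        if w >= w_obs - 1e-12:
            count += 1
    return count / total


def _window_frame(day_values, night_values):
    rows = []
    for i, v in enumerate(day_values):
        t = pd.Timestamp("2018-09-01 11:00") + pd.Timedelta(minutes=7 * i)
        rows.append(flux_row(t, t + pd.Timedelta(hours=1), v))
    for i, v in enumerate(night_values):
        t = pd.Timestamp("2018-09-01 01:00") + pd.Timedelta(minutes=7 * i)
        rows.append(flux_row(t, t + pd.Timedelta(hours=1), v))
    return pd.DataFrame(rows)


class TestWilcoxonDayNight:
    def test_identical_samples_p_at_least_half(self):
        res = wilcoxon_day_night(_window_frame([2, 3, 4], [2, 3, 4]), utc_offset=0.0)
        assert res.p_value >= 0.5

    def test_exact_small_sample_enumeration(self):
        res = wilcoxon_day_night(_window_frame([3, 4, 5], [1, 2]), utc_offset=0.0)
        assert res.method == "exact"
        assert res.p_value == pytest.approx(1 / 10)

    @pytest.mark.parametrize("seed", range(8))
    def test_exact_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_day, n_night = rng.integers(2, 5, size=2)
        day = rng.permutation(20)[:n_day].astype(float)
        night = (rng.permutation(20)[:n_night] + 0.5).astype(float)
        res = wilcoxon_day_night(_window_frame(day, night), utc_offset=0.0)
        assert res.method == "exact"
        assert res.p_value == pytest.approx(
            rank_sum_exact_p_greater(day, night), rel=1e-9
        )

    def test_empty_window_flagged(self):
        res = wilcoxon_day_night(_window_frame([1, 2, 3], []), utc_offset=0.0)
        assert not res.ok
        assert res.flag == "empty_window"

    def test_large_sample_uses_asymptotic(self):
        rng = np.random.default_rng(1)
        res = wilcoxon_day_night(
            _window_frame(rng.uniform(2, 3, 20), rng.uniform(1, 2, 20)),
            utc_offset=0.0,
        )
        assert res.method == "asymptotic"
        assert res.p_value < 0.001

    def test_midpoint_window_selection_respects_offset(self):
        # record 09:30-10:30 UTC has midpoint 10:00 UTC -> in day window only
        # with offset 0; with offset +3 it is 13:00 local, still in day window
        df = _window_frame([3, 4, 5], [1, 2])
        res0 = wilcoxon_day_night(df, utc_offset=0.0)
        res12 = wilcoxon_day_night(df, utc_offset=12.0)
        assert res0.n_day == 3
        # shifting by 12 h swaps the windows
        assert res12.n_day == 2


class TestFlrExceedance:
    def test_all_unit_ratios_is_degenerate(self):
        out = flr_exceedance_test([1.0, 1.0, 1.0, 1.0, 1.0])
        assert out["flag"] == "too_few_nonzero_differences"
        assert math.isnan(out["p_value"])
        assert out["fraction_gt"] == 0.0

    def test_all_greater_exact_p(self):
        out = flr_exceedance_test([2.0, 3.0, 4.0, 5.0, 6.0])
        assert out["p_value"] == pytest.approx(1 / 32)
        assert out["fraction_gt"] == 1.0

    def test_mixed_statistic_matches_brute_force(self):
        x = [0.5, 2.0, 2.0, 2.0]
        out = flr_exceedance_test(x)
        d = np.array(x) - 1.0
        ranks = pd.Series(np.abs(d)).rank().to_numpy()
        assert out["statistic"] == pytest.approx(ranks[d > 0].sum())

    @pytest.mark.parametrize("seed", range(6))
    def test_exact_matches_sign_enumeration(self, seed):
        rng = np.random.default_rng(100 + seed)
        x = 1.0 + rng.choice(np.arange(1, 40), size=6, replace=False) * rng.choice(
            [-0.01, 0.02], size=6
        )
        out = flr_exceedance_test(x)
        assert out["p_value"] == pytest.approx(signed_rank_exact_p_greater(x), rel=1e-9)

    def test_small_n_skips_test_but_reports_fraction(self):
        out = flr_exceedance_test([2.0, 3.0])
        assert out["flag"] == "too_few_nonzero_differences"
        assert out["fraction_gt"] == 1.0
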