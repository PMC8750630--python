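import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from taascan import assay_quant as aq, synthetic_data as sd


class TestFluorescenceIndex:
    def test_sample_equal_to_background_is_zero(self):
        fi = aq.fluorescence_index(250.0, 250.0)
        assert fi == 0.0 and not aq.is_binder(fi)

    def test_threefold_signal_gives_fi_two(self):
        fi = aq.fluorescence_index(300.0, 100.0)
        assert fi == pytest.approx(2.0) and aq.is_binder(fi)

    def test_threshold_is_strict(self):
        assert not aq.is_binder(0.5)
        assert aq.is_binder(0.5 + 1e-9)

    def test_non_positive_background_rejected(self):
        with pytest.raises(ValueError):
            aq.fluorescence_index(100.0, 0.0)

    @given(
        st.floats(min_value=1.0, max_value=1e5),
        st.floats(min_value=1.0, max_value=1e5),
        st.floats(min_value=1e-3, max_value=1e3),
    )
    @settings(max_examples=100, deadline=None)
    def test_scale_invariance(self, sample, background, scale):
        base = aq.fluorescence_index(sample, background)
        scaled = aq.fluorescence_index(scale * sample, scale * background)
        assert scaled == pytest.approx(base, rel=1e-9, abs=1e-9)


class TestBindingProfile:
    def test_saturating_curve_is_binder_and_monotone(self):
        series = sd.gen_binding_series(sd.SimulationConfig(seed=1), binder=True)
        profile = aq.binding_profile(series)
        assert profile.binder and profile.monotone
        assert all(b >= a for a, b in zip(profile.fi, profile.fi[1:]))

    def test_flat_negative_control_is_non_binder(self):
        series = sd.gen_binding_series(sd.SimulationConfig(seed=2), binder=False)
        profile = aq.binding_profile(series)
        assert not profile.binder

    def test_single_concentration_rejected(self):
        with pytest.raises(ValueError):
            aq.binding_profile(
                aq.BindingSeries("p", (50.0,), (300.0,), mfi_background=100.0)
            )


class TestPercentRemaining:
    def test_constant_series_stays_at_hundred(self):
        series = aq.DecaySeries("p", (0.0, 2.0, 4.0), (500.0, 500.0, 500.0))
        assert aq.percent_remaining(series) == (100.0, 100.0, 100.0)

    def test_halving_series_closed_form(self):
        series = aq.DecaySeries(
            "p", (0.0, 2.0, 4.0, 6.0, 8.0), (800.0, 400.0, 200.0, 100.0, 50.0)
        )
        assert aq.percent_remaining(series) == (100.0, 50.0, 25.0, 12.5, 6.25)

    def test_noisy_series_equals_elementwise_ratio(self):
        series = sd.gen_decay_series(3.0, noise_cv=0.2, seed=5)
        pct = aq.percent_remaining(series)
        expected = tuple(100.0 * m / series.mfi[0] for m in series.mfi)
        assert pct == pytest.approx(expected)


class TestDC50:
    def test_first_timepoint_at_or_below_half(self):
        series = aq.DecaySeries("p", (0.0, 2.0, 4.0, 6.0, 8.0), (100.0, 80.0, 45.0, 30.0, 20.0))
        result = aq.dc50(series)
        assert result.reached and result.hours == 4.0

    def test_not_reached_within_window(self):
        series = aq.DecaySeries("p", (0.0, 2.0, 4.0, 6.0, 8.0), (100.0, 90.0, 80.0, 70.0, 60.0))
        result = aq.dc50(series)
        assert not result.reached and result.hours is None
        assert "> 8" in str(result)

    def test_exact_exponential_half_life(self):
        series = sd.gen_decay_series(4.0, noise_cv=0.0)
        assert aq.dc50(series, "discrete").hours == 4.0
        assert aq.dc50(series, "interpolated").hours == pytest.approx(4.0)

    def test_interpolated_not_later_than_discrete(self):
        for seed in range(5):
            series = sd.gen_decay_series(3.0, noise_cv=0.1, seed=seed)
            discrete = aq.dc50(series, "discrete")
            interp = aq.dc50(series, "interpolated")
            if discrete.reached and interp.reached:
                assert interp.hours <= discrete.hours + 1e-12

    def test_unknown_mode_rejected(self):
        series = sd.gen_decay_series(4.0)
        with pytest.raises(ValueError):
            aq.dc50(series, "spline")


def make_events(n, positives, channel="M1"):
    """n gated events, the first `positives` positive in `channel`."""
    intensity = np.full(n, 100.0)
    intensity[:positives] = 10_000.0
    return aq.MultimerEventTable(
        donor_id="D1",
        group="HCC",
        events=pd.DataFrame(
            {"live": 1, "cd3": 5000.0, "cd8": 5000.0, channel: intensity}
        ),
    )


THRESHOLDS = aq.GatingThresholds(cd3=1000.0, cd8=1000.0, multimer={"M1": 1000.0})


class TestMultimerFrequencies:
    def test_nine_in_thousand_is_point_nine_percent(self):
        result = aq.multimer_frequencies(make_events(1000, 9), THRESHOLDS)
        assert result.percent["M1"] == pytest.approx(0.9)
        assert result.n_gated == 1000

    def test_zero_positives(self):
        result = aq.multimer_frequencies(make_events(1000, 0), THRESHOLDS)
        assert result.percent["M1"] == 0.0

    def test_empty_gate_rejected(self):
        table = make_events(10, 1)
        table.events["live"] = 0
        with pytest.raises(ValueError, match="gate"):
            aq.multimer_frequencies(table, THRESHOLDS)

    def test_unknown_pair_channel_rejected(self):
        with pytest.raises(ValueError, match="pair"):
            aq.multimer_frequencies(
                make_events(100, 1), THRESHOLDS, pairs={"bad": ("M1", "M9")}
            )

    def test_planted_frequencies_recovered_within_binomial_ci(self):
        cfg = sd.SimulationConfig(seed=6, n_events=50_000)
        freq = {"TAA": 0.01, "VIRAL": 0.005}
        cross = {"pair": ("TAA", "VIRAL", 0.002)}
        table = sd.gen_multimer_events(cfg, "D1", "HCC", freq, cross, seed=7)
        thresholds = aq.GatingThresholds(
            cd3=1000.0, cd8=1000.0, multimer={"TAA": 1000.0, "VIRAL": 1000.0}
        )
        result = aq.multimer_frequencies(table, thresholds, pairs={"pair": ("TAA", "VIRAL")})
        n = result.n_gated
        for channel, p in freq.items():
            half = 100 * 1.96 * np.sqrt(p * (1 - p) / n)
            assert abs(result.percent[channel] - 100 * p) <= half
        assert result.cross_percent["pair"] <= min(result.percent.values())

    def test_percentages_bounded_and_cross_below_singles(self):
        cfg = sd.SimulationConfig(seed=8, n_events=20_000)
        table = sd.gen_multimer_events(
            cfg, "D1", "HCC", {"A": 0.02, "B": 0.01}, {"x": ("A", "B", 0.008)}, seed=9
        )
        thresholds = aq.GatingThresholds(1000.0, 1000.0, {"A": 1000.0, "B": 1000.0})
        result = aq.multimer_frequencies(table, thresholds, pairs={"x": ("A", "B")})
        assert all(0.0 <= v <= 100.0 for v in result.percent.values())
        assert result.cross_percent["x"] <= min(result.percent["A"], result.percent["B"])


class TestGroupSummary:
    def make_result(self, donor, group, pct):
        return aq.MultimerResult(
            donor_id=donor, group=group, n_gated=1000, percent={"M1": pct}
        )

    def test_single_donor_mean_is_identity(self):
        summary = aq.group_summary([self.make_result("D1", "HCC", 0.9)])
        assert summary["HCC"].mean_percent["M1"] == 0.9
        assert summary["HCC"].n_donors == 1

    def test_two_donor_mean(self):
        summary = aq.group_summary(
            [self.make_result("D1", "HCC", 0.8), self.make_result("D2", "HCC", 0.96)]
        )
        assert summary["HCC"].mean_percent["M1"] == pytest.approx(0.88)

    def test_groups_kept_separate(self):
        summary = aq.group_summary(
            [self.make_result("D1", "HCC", 0.8), self.make_result("H1", "healthy", 0.1)]
        )
        assert summary["HCC"].mean_percent["M1"] == 0.8
        assert summary["healthy"].mean_percent["M1"] == 0.1


def test_average_replicates_reports_sem():
    table = pd.DataFrame(
        {"peptide": ["p"] * 6, "x": [0, 0, 0, 2, 2, 2], "mfi": [90, 100, 110, 40, 50, 60]}
    )
    out = aq.average_replicates(table)
    assert list(out["mfi"]) == [100.0, 50.0]
    assert list(out["n_replicates"]) == [3, 3]
    assert out["mfi_sem"].iloc[0] == pytest.approx(np.std([90, 100, 110], ddof=1) / np.sqrt(3))
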