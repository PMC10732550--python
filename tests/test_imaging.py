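"""dF/F, detrending, deconvolution and trial-shuffle statistics."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import rfneurostim as rf
from rfneurostim import imaging


def _dff(values, dt=1 / 30):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    t = np.arange(values.shape[1]) * dt
    return imaging.DffTrace(dff=values, timestamps=t,
                            unit_ids=np.arange(values.shape[0]))


class TestDff:
    def test_constant_trace_is_zero(self):
        out = rf.compute_dff(np.full((1, 10), 7.0), np.arange(10) / 30)
        assert np.all(out.dff == 0)

    def test_arithmetic_example(self):
        out = rf.compute_dff(np.array([[1.0, 2.0, 3.0]]), np.arange(3) / 30)
        assert np.allclose(out.dff, [[-0.5, 0.0, 0.5]])

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        F = rng.uniform(1, 5, size=(2, 100))
        t = np.arange(100) / 30
        a = rf.compute_dff(F, t)
        b = rf.compute_dff(3.7 * F, t)
        assert np.allclose(a.dff, b.dff, atol=1e-12)

    @given(st.lists(st.floats(0.1, 100.0), min_size=3, max_size=50))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_median_exactly_zero(self, values):
        out = rf.compute_dff(np.array([values]), np.arange(len(values)) / 30)
        if len(values) % 2 == 1:
            assert np.median(out.dff[0]) == 0.0
        else:
            # even-length medians average two frames: exact up to rounding
            assert abs(np.median(out.dff[0])) < 1e-12

    def test_nonpositive_median_raises(self):
        with pytest.raises(ValueError, match="median"):
            rf.compute_dff(np.array([[-1.0, 0.0, 1.0]]), np.arange(3) / 30)


class TestDetrend:
    def test_pure_bleach_trend_removed(self):
        t = np.arange(0, 600, 1 / 30)
        trend = np.exp(-t / 1200.0)
        out = rf.detrend(_dff(trend), window_s=30.0)
        interior = (t > 30) & (t < t[-1] - 30)
        assert np.max(np.abs(out.dff[0][interior])) < 0.01

    def test_trend_free_trace_nearly_unchanged(self):
        rng = np.random.default_rng(2)
        noise_sd = 0.05
        y = rng.normal(0, noise_sd, 30 * 300)
        out = rf.detrend(_dff(y), window_s=30.0)
        assert np.max(np.abs(out.dff[0] - y)) < noise_sd

    def test_all_zero_stays_zero(self):
        out = rf.detrend(_dff(np.zeros(3000)), window_s=30.0)
        assert np.all(out.dff == 0)

    def test_window_too_short_raises(self):
        with pytest.raises(ValueError):
            rf.detrend(_dff(np.zeros(100)), window_s=0.01)


class TestDeconvolve:
    def test_zero_trace_zero_events(self):
        dec = rf.deconvolve(_dff(np.zeros(500)))
        assert np.all(dec.events == 0)

    def test_single_ar1_transient_recovered(self):
        gamma = 0.95
        n = 1000
        y = np.zeros(n)
        y[100:] = gamma ** np.arange(n - 100)
        dec = rf.deconvolve(_dff(y))
        ev = dec.events[0]
        assert ev[100] == pytest.approx(1.0, rel=0.01)
        other = np.delete(ev, 100)
        assert other.max() < 0.01

    def test_nonuniform_timestamps_raise(self):
        t = np.arange(100) / 30.0
        t[50] += 0.02
        trace = imaging.DffTrace(dff=np.zeros((1, 100)), timestamps=t,
                                 unit_ids=np.array([0]))
        with pytest.raises(ValueError, match="uniform"):
            rf.deconvolve(trace)

    def test_only_ar1_supported(self):
        with pytest.raises(ValueError):
            rf.deconvolve(_dff(np.zeros(100)), ar_order=2)

    def test_event_recovery_on_synthetic_session(self):
        # full 300-trial session at SNR 5: binned recovered events correlate
        # with ground-truth spike counts
        protocol = rf.make_protocol(300, 3, 3, 37.5)
        spec = rf.PopulationSpec.uniform(3, 0.4, 1.0, seed=12)
        spikes = rf.generate_spike_trains(protocol, spec)
        kernel = rf.CalciumKernelSpec(unit_amplitude=1.0, noise_sd=0.2)
        fluor = rf.generate_calcium(spikes, kernel, protocol.session_length, seed=13)
        dff = rf.detrend(rf.compute_dff(fluor.F, fluor.timestamps, fluor.unit_ids))
        dec = rf.threshold_events(rf.deconvolve(dff), k_mad=3.0)
        bins = np.arange(0, protocol.session_length + 1e-9, 20 / 30.0)
        for u in range(3):
            gt, _ = np.histogram(spikes.spike_times[u], bins)
            idx = np.searchsorted(dec.timestamps, bins[:-1])
            rec = np.add.reduceat(dec.events[u], idx)
            r = stats.pearsonr(gt, rec[:gt.size]).statistic
            assert r > 0.8


class TestThreshold:
    def test_k_zero_is_identity(self):
        dec = rf.deconvolve(_dff(np.abs(np.sin(np.arange(300) / 5.0))))
        out = rf.threshold_events(dec, k_mad=0)
        assert np.array_equal(out.events, dec.events)

    def test_k_inf_zeroes_everything(self):
        rng = np.random.default_rng(1)
        dec = rf.deconvolve(_dff(rng.normal(0, 0.1, 600)))
        out = rf.threshold_events(dec, k_mad=math.inf)
        assert np.all(out.events == 0)

    def test_large_noiseless_event_retained(self):
        gamma = 0.95
        y = np.zeros(400)
        y[200:] = 5.0 * gamma ** np.arange(200)
        y += np.random.default_rng(2).normal(0, 0.01, 400)
        dec = rf.deconvolve(_dff(y), gamma=gamma)
        out = rf.threshold_events(dec, k_mad=3.0)
        assert out.events[0, 200] == pytest.approx(5.0, rel=0.05)

    def test_negative_k_raises(self):
        dec = rf.deconvolve(_dff(np.zeros(100)))
        with pytest.raises(ValueError):
            rf.threshold_events(dec, k_mad=-1)


class TestExcludePeriods:
    def test_empty_list_is_identity(self):
        trace = _dff(np.ones(100))
        out = rf.exclude_periods(trace, [])
        assert np.array_equal(out.dff, trace.dff)
        assert out.excluded_periods == [[]]

    def test_masked_trial_dropped_from_metrics(self):
        protocol = rf.make_protocol(10, 3, 3, 0)
        trace = _dff(np.ones(int(protocol.session_length * 30)))
        # trial 5 spans [30, 36)
        out = rf.exclude_periods(trace, [(31.0, 32.0)])
        values = imaging.epoch_metric(out, protocol, "auc")
        assert not values.usable[0, 5]
        assert values.usable[0].sum() == 9

    def test_mask_everything_excludes_unit(self):
        protocol = rf.make_protocol(30, 3, 3, 0)
        trace = _dff(np.ones(int(protocol.session_length * 30)))
        out = rf.exclude_periods(trace, [(0.0, protocol.session_length)])
        values = imaging.epoch_metric(out, protocol, "auc")
        table, results = imaging.shuffle_test_set(values, n_shuffles=100, seed=0)
        assert bool(table.excluded.iloc[0])
        assert math.isnan(table.p_value.iloc[0])

    def test_inverted_interval_raises(self):
        with pytest.raises(ValueError, match="inverted"):
            rf.exclude_periods(_dff(np.ones(100)), [(2.0, 1.0)])


class TestEpochMetric:
    def test_unit_dff_auc_closed_form(self):
        protocol = rf.make_protocol(4, 3, 3, 0)
        trace = _dff(np.ones(int(protocol.session_length * 30)))
        values = imaging.epoch_metric(trace, protocol, "auc")
        assert np.allclose(values.on_values, 3.0, atol=1 / 30)
        assert np.allclose(values.off_values, 3.0, atol=1 / 30)

    def test_event_metrics(self):
        protocol = rf.make_protocol(2, 3, 3, 0)
        n = int(protocol.session_length * 30)
        events = np.zeros((1, n))
        events[0, 10] = 2.5  # inside trial 0 ON epoch
        dec = imaging.DeconvolvedActivity(
            events=events, gamma=np.array([0.95]), noise_scale=np.array([0.1]),
            timestamps=np.arange(n) / 30.0, unit_ids=np.array([0]))
        amp = imaging.epoch_metric(dec, protocol, "spike_amp_sum")
        cnt = imaging.epoch_metric(dec, protocol, "spike_count")
        assert amp.on_values[0, 0] == 2.5 and cnt.on_values[0, 0] == 1
        assert amp.off_values.sum() == 0 and cnt.on_values[0, 1] == 0

    def test_unknown_metric_raises(self):
        protocol = rf.make_protocol(2, 3, 3, 0)
        with pytest.raises(ValueError, match="unknown metric"):
            imaging.epoch_metric(_dff(np.ones(360)), protocol, "median")


class TestShuffleTest:
    def test_extreme_suppression(self):
        off = np.full(40, 5.0)
        on = np.zeros(40)
        res = rf.shuffle_test(on, off, n_shuffles=1000, seed=1)
        assert res.observed_mi == -1.0
        assert res.p_value == pytest.approx(1 / 1001)
        assert res.affected

    def test_identical_values_null(self):
        vals = np.linspace(1, 4, 30)
        res = rf.shuffle_test(vals, vals, n_shuffles=500, seed=2)
        assert res.observed_mi == 0.0
        assert res.p_value > 0.9
        assert not res.affected

    def test_all_zero_excluded(self):
        res = rf.shuffle_test(np.zeros(25), np.zeros(25), n_shuffles=200, seed=3)
        assert res.excluded and math.isnan(res.p_value)

    def test_too_few_trials_raise(self):
        with pytest.raises(ValueError, match="trials"):
            rf.shuffle_test(np.ones(5), np.ones(5))

    def test_monte_carlo_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(9)
        on = rng.gamma(2.0, 1.0, 8)
        off = rng.gamma(2.0, 1.0, 8)
        exact = imaging.exhaustive_shuffle_null(on, off)
        res = rf.shuffle_test(on, off, n_shuffles=4000, seed=10, min_trials=8)
        mc = res.null_mis
        se_mean = exact.std() / math.sqrt(mc.size)
        se_sd = exact.std() / math.sqrt(2 * mc.size)
        assert abs(mc.mean() - exact.mean()) < 3 * se_mean
        assert abs(mc.std() - exact.std()) < 3 * se_sd

    def test_p_values_uniform_under_exchangeable_null(self):
        n_sims = 1000
        children = np.random.SeedSequence(77).spawn(n_sims)
        ps = np.empty(n_sims)
        for i in range(n_sims):
            r = np.random.default_rng(children[i])
            on = r.gamma(2.0, 1.0, 40)
            off = r.gamma(2.0, 1.0, 40)
            ps[i] = rf.shuffle_test(on, off, n_shuffles=300,
                                    seed=int(r.integers(2 ** 31))).p_value
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestCompareConditions:
    @staticmethod
    def _null_table(n_units, lam, seed, n_sessions=1):
        rng = np.random.default_rng(seed)
        on = rng.poisson(lam, n_units)
        off = rng.poisson(lam, n_units)
        mi = (on - off) / np.maximum(on + off, 1)
        return pd.DataFrame({
            "mi": mi, "affected": np.zeros(n_units, bool),
            "session": np.arange(n_units) % n_sessions})

    def test_identical_inputs_give_p_one(self):
        tab = self._null_table(100, 400, 1)
        out = rf.compare_conditions(tab, tab.copy())
        assert out["rank_sum_p_mi"] == pytest.approx(1.0, abs=0.02)

    def test_null_vs_null_not_significant_usually(self):
        a = self._null_table(400, 400, 2, n_sessions=4)
        b = self._null_table(400, 400, 3, n_sessions=4)
        out = rf.compare_conditions(a, b)
        assert out["rank_sum_p_mi"] > 0.001
        assert np.isfinite(out["rank_sum_p_percent_affected"])

    def test_suppressed_population_detected(self):
        rng = np.random.default_rng(5)
        n = 300
        on = rng.poisson(400, n).astype(float)
        on[:90] = rng.poisson(200, 90)  # 30% suppressed at multiplier 0.5
        off = rng.poisson(400, n)
        stim = pd.DataFrame({"mi": (on - off) / (on + off),
                             "affected": np.zeros(n, bool)})
        sham = self._null_table(n, 400, 6)
        out = rf.compare_conditions(stim, sham)
        assert out["rank_sum_p_mi"] < 0.001

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            rf.compare_conditions(pd.DataFrame(), self._null_table(10, 10, 1))


class TestCombineSessions:
    @staticmethod
    def _session(seed, n_units=5, n_trials=150, lam=2.0):
        rng = np.random.default_rng(seed)
        return {u: (rng.poisson(lam, n_trials).astype(float),
                    rng.poisson(lam, n_trials).astype(float))
                for u in range(n_units)}

    def test_pooling_doubles_trials(self):
        a, b = self._session(1), self._session(2)
        table, dropped = rf.combine_sessions(a, b, {u: u for u in a},
                                             n_shuffles=200, seed=3)
        assert (table.n_trials == 300).all()
        assert dropped == []

    def test_unmapped_units_dropped_and_reported(self):
        a, b = self._session(1, n_units=4), self._session(2, n_units=4)
        table, dropped = rf.combine_sessions(a, b, {0: 0, 1: 1},
                                             n_shuffles=200, seed=3)
        assert len(table) == 2
        assert set(dropped) == {2, 3}

    def test_duplicate_mapping_raises(self):
        a, b = self._session(1), self._session(2)
        with pytest.raises(ValueError, match="injective"):
            rf.combine_sessions(a, b, {0: 0, 1: 0})

    def test_empty_map_empty_result(self):
        a, b = self._session(1), self._session(2)
        table, dropped = rf.combine_sessions(a, b, {}, n_shuffles=200, seed=3)
        assert len(table) == 0
        assert set(dropped) == set(a) | set(b)

    def test_pooled_type_one_error_unchanged(self):
        # pooling two null sessions must not inflate false positives
        n_units = 200
        rng = np.random.default_rng(11)
        a = {u: (rng.poisson(2.0, 150).astype(float),
                 rng.poisson(2.0, 150).astype(float)) for u in range(n_units)}
        b = {u: (rng.poisson(2.0, 150).astype(float),
                 rng.poisson(2.0, 150).astype(float)) for u in range(n_units)}
        table, _ = rf.combine_sessions(a, b, {u: u for u in a},
                                       n_shuffles=500, seed=12)
        assert table.affected.mean() <= 0.08


class TestBackgroundQc:
    def _movie(self, artifact, n_trials=20):
        protocol = rf.make_protocol(n_trials, 3, 3, 37.5)
        n_frames = int(protocol.session_length * 30)
        F = np.zeros((2, n_frames))
        fluor = rf.FluorescenceSet(F=F, timestamps=np.arange(n_frames) / 30.0,
                                   unit_ids=np.arange(2))
        return rf.generate_movie(fluor, artifact, protocol, shape=(24, 24),
                                 seed=7), protocol

    def test_clean_movie_not_flagged(self):
        movie, protocol = self._movie(0.0)
        out = rf.background_artifact_qc(movie, protocol, seed=1)
        assert abs(out["percent_change"]) < 0.2
        assert not out["flagged"]

    def test_four_percent_dip_detected(self):
        movie, protocol = self._movie(0.04)
        out = rf.background_artifact_qc(movie, protocol, seed=1)
        assert out["percent_change"] == pytest.approx(-4.0, abs=0.5)
        assert out["significant"] and out["flagged"]

    def test_constant_background_trace_exact_zero(self):
        protocol = rf.make_protocol(10, 3, 3, 0)
        t = np.arange(int(protocol.session_length * 10)) / 10.0
        out = rf.background_artifact_qc(np.full(t.size, 123.0), protocol,
                                        timestamps=t, seed=2)
        assert out["percent_change"] == 0.0
        assert not out["flagged"]

    def test_bare_trace_needs_timestamps(self):
        protocol = rf.make_protocol(10, 3, 3, 0)
        with pytest.raises(ValueError, match="timestamps"):
            rf.background_artifact_qc(np.ones(100), protocol)
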