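"""Light-response pipeline: filtering, detection, windowing, activation
classification, response ratio and group comparison."""

import numpy as np
import pandas as pd
import pytest
from scipy import signal as sps

from retinakit import mea, synth
from retinakit._ranksum import rank_sum_test


def _sine_rec(freq, fs=25000.0, dur=2.0):
    t = np.arange(int(dur * fs)) / fs
    return mea.RawRecording(voltage=np.sin(2 * np.pi * freq * t)[None, :], sampling_rate=fs)


class TestBandpassFilter:
    def test_midband_gain_near_unity(self):
        rec = _sine_rec(1500.0)
        out = mea.bandpass_filter(rec, mea.FilterSpec(direction="forward"))
        amp = np.max(np.abs(out.voltage[0, 20000:30000]))  # steady state
        assert amp == pytest.approx(1.0, abs=0.02)

    def test_dc_rejected(self):
        rec = mea.RawRecording(voltage=np.ones((1, 50000)), sampling_rate=25000.0)
        out = mea.bandpass_filter(rec)
        assert np.max(np.abs(out.voltage[0, 10000:])) < 1e-3

    def test_50hz_single_pass_matches_closed_form(self):
        """Order-2 high-pass skirt at 50 Hz: |H| = 1/sqrt(1 + (400/50)^4)."""
        rec = _sine_rec(50.0, dur=4.0)
        out = mea.bandpass_filter(rec, mea.FilterSpec(direction="forward"))
        amp = np.max(np.abs(out.voltage[0, 50000:]))
        expected = 1.0 / np.sqrt(1.0 + (400.0 / 50.0) ** 4)
        assert amp == pytest.approx(expected, rel=0.01)

    def test_band_edge_above_nyquist_rejected(self):
        rec = _sine_rec(100.0, fs=8000.0)
        with pytest.raises(ValueError):
            mea.bandpass_filter(rec, mea.FilterSpec(high=5000.0))

    def test_shape_preserved(self, short_protocol):
        model = synth.RateModel.flat([1e14], on_rate=10.0, spont_rate=1.0)
        rec, _ = synth.simulate_trace(short_protocol, model, synth.biphasic_template(25000.0), 1e-5, seed=0)
        out = mea.bandpass_filter(rec)
        assert out.voltage.shape == rec.voltage.shape


class TestDetectSpikes:
    def test_injected_spikes_recovered_with_timing(self, short_protocol):
        """Three large spikes in low noise: exactly 3 events within 0.2 ms."""
        fs = 25000.0
        tpl = synth.biphasic_template(fs, amplitude_sd=8.0)
        n = int(6.0 * fs)
        rng = np.random.default_rng(0)
        noise_sd = 1e-5
        trace = rng.normal(0, noise_sd, n)
        truth = [1.0, 2.5, 4.0]
        for t0 in truth:
            i = int(t0 * fs)
            trace[i : i + len(tpl.waveform)] += tpl.waveform * noise_sd
        rec = mea.RawRecording(voltage=trace[None, :], sampling_rate=fs)
        filtered = mea.bandpass_filter(rec)
        train = mea.detect_spikes(filtered)
        assert len(train.times[0]) == 3
        for det, t0 in zip(train.times[0], truth):
            assert abs(det - t0) < 2e-4

    def test_dead_time_suppresses_close_events(self):
        fs = 25000.0
        trace = np.random.default_rng(1).normal(0, 1.0, int(fs)) * 0.1
        for t0 in (0.5, 0.501):  # 1.0 ms apart
            trace[int(t0 * fs)] = 10.0
        rec = mea.RawRecording(voltage=trace[None, :], sampling_rate=fs)
        train = mea.detect_spikes(rec, mea.DetectionSpec(dead_time=0.0015))
        near = train.times[0][(train.times[0] > 0.49) & (train.times[0] < 0.52)]
        assert len(near) == 1

    def test_false_rate_on_pure_noise_within_monte_carlo_bound(self):
        """k = 5 on white Gaussian noise: false events below an empirical
        bound from an independent Monte-Carlo oracle on the same noise."""
        fs = 25000.0
        n = int(20 * fs)
        rng = np.random.default_rng(2)
        # oracle: count 5-sigma upward threshold crossings on fresh noise
        oracle_rates = []
        for _ in range(5):
            x = rng.standard_normal(n)
            above = np.abs(x) >= 5.0
            crossings = np.count_nonzero(above[1:] & ~above[:-1])
            oracle_rates.append(crossings / (n / fs))
        bound = 3 * max(np.mean(oracle_rates), 1.0 / (n / fs))
        trace = np.random.default_rng(3).standard_normal(n)
        rec = mea.RawRecording(voltage=trace[None, :], sampling_rate=fs)
        train = mea.detect_spikes(rec)
        rate = len(train.times[0]) / (n / fs)
        assert rate <= bound

    def test_zero_variance_channel_flagged(self):
        rec = mea.RawRecording(voltage=np.zeros((1, 1000)), sampling_rate=25000.0)
        train = mea.detect_spikes(rec)
        assert train.flagged_channels == (0,)
        assert len(train.times[0]) == 0


class TestWindowCounts:
    def test_single_spike_in_on_window(self):
        p = synth.make_protocol(intensities=[1.0], reps=1, flash_dur=0.35, dark_gap=2.0)
        train = mea.SpikeTrain(times={0: np.array([2.1])}, duration_s=5.0)
        df = mea.window_counts(train, p)
        assert df.loc[0, ["count_on", "count_off", "count_spont"]].tolist() == [1, 0, 0]

    def test_empty_train_all_zero(self, paper_protocol):
        train = mea.SpikeTrain(times={0: np.empty(0)}, duration_s=400.0)
        df = mea.window_counts(train, paper_protocol)
        assert (df[["count_on", "count_off", "count_spont"]] == 0).all().all()

    def test_matches_brute_force_oracle(self, paper_protocol, rng):
        """Random 500-spike train: counts equal exhaustive interval membership."""
        ts = np.sort(rng.uniform(0, paper_protocol.total_duration_s, 500))
        train = mea.SpikeTrain(times={0: ts}, duration_s=paper_protocol.total_duration_s)
        df = mea.window_counts(train, paper_protocol)
        w = paper_protocol.flash_duration_s
        for _, row in df.iterrows():
            epoch = next(
                e
                for e in paper_protocol.epochs
                if e.intensity == row["intensity"] and e.rep_index == row["rep_index"]
            )
            on = np.sum((ts >= epoch.onset_s) & (ts < epoch.onset_s + w))
            off = np.sum((ts >= epoch.offset_s) & (ts < epoch.offset_s + w))
            sp = np.sum((ts >= epoch.onset_s - w) & (ts < epoch.onset_s))
            assert (row["count_on"], row["count_off"], row["count_spont"]) == (on, off, sp)

    def test_overlapping_windows_rejected(self):
        p = synth.make_protocol(intensities=[1.0], reps=2, flash_dur=0.35, dark_gap=2.0)
        squeezed = synth.StimulusProtocol(
            epochs=tuple(
                synth.FlashEpoch(e.onset_s * 0.2, e.duration_s, e.intensity, e.rep_index)
                for e in p.epochs
            ),
            dark_gap_s=0.4,
        )
        train = mea.SpikeTrain(times={0: np.empty(0)}, duration_s=10.0)
        with pytest.raises(ValueError, match="overlap"):
            mea.window_counts(train, squeezed)


def _counts_frame(on, spont, off=None, channel=0, intensity=1.0):
    off = off if off is not None else [0] * len(on)
    df = pd.DataFrame(
        {
            "channel_id": channel,
            "intensity": intensity,
            "rep_index": range(len(on)),
            "count_on": on,
            "count_off": off,
            "count_spont": spont,
        }
    )
    df.attrs["window_s"] = 0.35
    return df


class TestActivation:
    def test_identical_counts_not_activated(self):
        df = _counts_frame(on=[5] * 10, spont=[5] * 10)
        res = mea.test_activation(df)
        assert res.loc[0, "t_on"] == 0.0
        assert not res.loc[0, "on_activated"]

    def test_constant_positive_difference_activates(self):
        """Zero-variance differences with positive mean: t = +inf, activated."""
        df = _counts_frame(on=[10, 11, 12, 13], spont=[5, 6, 7, 8])
        res = mea.test_activation(df)
        assert np.isposinf(res.loc[0, "t_on"])
        assert res.loc[0, "on_activated"]

    def test_constant_negative_difference_not_activated(self):
        df = _counts_frame(on=[1, 2, 3, 4], spont=[5, 6, 7, 8])
        res = mea.test_activation(df)
        assert np.isneginf(res.loc[0, "t_on"])
        assert not res.loc[0, "on_activated"]

    def test_strong_response_detected_in_nearly_all_simulations(self):
        """ON ~ Poisson(10) vs spont ~ Poisson(2), 20 reps: activation in > 99%."""
        rng = np.random.default_rng(42)
        hits = 0
        n_sim = 500
        for _ in range(n_sim):
            df = _counts_frame(on=rng.poisson(10, 20), spont=rng.poisson(2, 20))
            hits += int(mea.test_activation(df).loc[0, "on_activated"])
        assert hits / n_sim > 0.99

    def test_requires_two_reps(self):
        df = _counts_frame(on=[5], spont=[3])
        with pytest.raises(ValueError):
            mea.test_activation(df)


class TestSelectChannels:
    @pytest.mark.parametrize(
        "flags,included",
        [((True, True, True, False, False), True), ((True, True, False, False, False), False), ((False,) * 5, False)],
    )
    def test_three_of_five_rule(self, paper_protocol, flags, included):
        act = pd.DataFrame(
            {
                "channel_id": 0,
                "intensity": paper_protocol.photopic,
                "on_activated": flags,
            }
        )
        sel = mea.select_channels(act, paper_protocol)
        assert bool(sel.loc[0, "included"]) is included

    def test_threshold_rescales_for_short_protocols(self):
        p = synth.make_protocol(intensities=[1.0, 2.0, 3.0], reps=2, flash_dur=0.35, dark_gap=2.0)
        act = pd.DataFrame(
            {"channel_id": 0, "intensity": [1.0, 2.0, 3.0], "on_activated": [True, True, False]}
        )
        with pytest.warns(UserWarning, match="rescaled"):
            sel = mea.select_channels(act, p)
        assert bool(sel.loc[0, "included"])  # ceil(3/5*3) = 2 of 3


class TestResponseRatio:
    def test_equal_rates_give_zero(self):
        df = _counts_frame(on=[7, 7], spont=[7, 7])
        rr = mea.response_ratio(df)
        assert rr.loc[0, "ratio"] == pytest.approx(0.0)

    def test_zero_spont_gives_one(self):
        df = _counts_frame(on=[5, 5], spont=[0, 0])
        assert mea.response_ratio(df).loc[0, "ratio"] == pytest.approx(1.0)

    def test_paper_formula_at_50_vs_5(self):
        """rate_on 50 /s, rate_spont 5 /s -> ratio 45/55 = 0.8182."""
        df = _counts_frame(on=[17, 18], spont=[1.5, 2.0])  # means 17.5, 1.75 in 0.35 s
        rr = mea.response_ratio(df)
        assert rr.loc[0, "ratio"] == pytest.approx(45.0 / 55.0, abs=1e-12)

    def test_both_zero_undefined(self):
        df = _counts_frame(on=[0, 0], spont=[0, 0])
        assert np.isnan(mea.response_ratio(df).loc[0, "ratio"])

    def test_invariant_under_common_rate_rescaling(self):
        df1 = _counts_frame(on=[10, 20], spont=[2, 4])
        df2 = _counts_frame(on=[30, 60], spont=[6, 12])
        r1 = mea.response_ratio(df1).loc[0, "ratio"]
        r2 = mea.response_ratio(df2).loc[0, "ratio"]
        assert r1 == pytest.approx(r2)

    def test_selection_filters_channels(self):
        df = pd.concat(
            [_counts_frame(on=[5, 5], spont=[1, 1], channel=0), _counts_frame(on=[5, 5], spont=[1, 1], channel=1)]
        )
        df.attrs["window_s"] = 0.35
        sel = pd.DataFrame({"channel_id": [0, 1], "n_photopic_activated": [5, 0], "included": [True, False]})
        rr = mea.response_ratio(df, sel)
        assert set(rr["channel_id"]) == {0}


class TestCompareGroups:
    def test_identical_samples_p_one(self):
        base = _counts_frame(on=[5, 5], spont=[1, 1])
        rr = mea.response_ratio(base)
        res = mea.compare_groups(rr, rr.copy())
        assert res.loc[0, "p_value"] == pytest.approx(1.0)

    def test_exact_two_vs_two_enumeration(self):
        """{1,2} vs {3,4}: two-sided exact p = 2/6."""
        stat, p = rank_sum_test([1.0, 2.0], [3.0, 4.0])
        assert p == pytest.approx(1.0 / 3.0)
        assert stat == 3.0

    def test_null_p_values_uniform(self):
        """Same-distribution groups of 150: p uniform across 500 seeded runs
        (KS against U(0,1))."""
        from scipy import stats as ss

        rng = np.random.default_rng(7)
        pvals = []
        for _ in range(500):
            x, y = rng.normal(size=150), rng.normal(size=150)
            pvals.append(rank_sum_test(x, y)[1])
        assert ss.kstest(pvals, "uniform").pvalue > 0.01

    def test_empty_group_raises(self):
        rr = mea.response_ratio(_counts_frame(on=[5, 5], spont=[1, 1]))
        empty = rr.copy()
        empty["ratio"] = np.nan
        with pytest.raises(ValueError, match="intensity"):
            mea.compare_groups(rr, empty)

    def test_exact_matches_scipy_without_ties(self):
        rng = np.random.default_rng(11)
        from scipy import stats as ss

        for _ in range(20):
            x, y = rng.normal(size=8), rng.normal(size=6)
            _, p = rank_sum_test(x, y)
            ref = ss.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
            assert p == pytest.approx(ref, abs=1e-12)


class TestEndToEnd:
    def test_detection_sensitivity_and_precision_at_8x_noise(self, short_protocol):
        """Full trace pipeline at 8x noise amplitude: sensitivity and
        precision >= 0.99 against ground truth."""
        model = synth.RateModel.flat([1e14], on_rate=30.0, spont_rate=8.0)
        tpl = synth.biphasic_template(25000.0, amplitude_sd=8.0)
        tp = fp = fn = 0
        for seed in range(4):
            rec, truth = synth.simulate_trace(short_protocol, model, tpl, noise_sd=1e-5, seed=seed)
            train = mea.detect_spikes(mea.bandpass_filter(rec))
            det = train.times[0]
            true_t = np.sort(truth["t_s"].to_numpy())
            used = np.zeros(len(det), dtype=bool)
            for t0 in true_t:
                j = np.searchsorted(det, t0)
                cand = [k for k in (j - 1, j) if 0 <= k < len(det) and not used[k] and abs(det[k] - t0) < 5e-4]
                if cand:
                    used[min(cand, key=lambda k: abs(det[k] - t0))] = True
                    tp += 1
                else:
                    fn += 1
            fp += int(np.sum(~used))
        assert tp / (tp + fn) >= 0.99
        assert tp / (tp + fp) >= 0.99

    def test_median_ratio_monotone_in_generator_rate_ratio(self, paper_protocol):
        """Higher ON/spont generator ratios yield higher median response ratios."""
        medians = []
        for on_rate in (10.0, 20.0, 40.0, 80.0):
            model = synth.RateModel.flat(paper_protocol.intensities, on_rate=on_rate, spont_rate=5.0)
            counts = synth.simulate_trial_counts(paper_protocol, model, n_channels=40, seed=21)
            act = mea.test_activation(counts)
            sel = mea.select_channels(act, paper_protocol)
            rr = mea.response_ratio(counts, sel)
            medians.append(np.nanmedian(rr["ratio"]))
        assert medians == sorted(medians)
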