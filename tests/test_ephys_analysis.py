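"""Event detection, charge integration and the statistics ladder."""

import numpy as np
import pytest

from synucleo import synthetic_data as sd
from synucleo.ephys_analysis import (
    DetectionParams,
    Event,
    Recording,
    charge_transferred,
    compare_groups,
    detect_events,
    read_recording,
    summarize,
    write_recording,
)

FS = 2000.0


def _inject(trace, fs, t0, amp, rise_ms=2.0, decay_ms=10.0):
    tau_r, tau_d = rise_ms * 1e-3, decay_ms * 1e-3
    t = np.arange(0, 8 * tau_d, 1 / fs)
    k = np.exp(-t / tau_d) - np.exp(-t / tau_r)
    k /= k.max()
    i0 = int(round(t0 * fs))
    seg = k[: len(trace) - i0]
    trace[i0 : i0 + len(seg)] -= amp * seg


class TestDetectEvents:
    def test_flat_trace_no_events(self):
        rec = Recording(FS, np.zeros(int(60 * FS)))
        assert detect_events(rec) == []

    def test_three_injected_events_recovered(self):
        trace = np.zeros(int(60 * FS))
        onsets = [10.0, 25.0, 40.0]
        for t0 in onsets:
            _inject(trace, FS, t0, 100.0)
        events = detect_events(Recording(FS, trace))
        assert len(events) == 3
        # peak occurs ~3.2 ms after onset for 2/10 ms kinetics
        for ev, t0 in zip(events, onsets):
            assert abs(ev.peak_time - (t0 + 0.0032)) < 1e-3
            assert ev.amplitude == pytest.approx(100.0, rel=0.05)

    def test_subthreshold_event_excluded(self):
        trace = np.zeros(int(30 * FS))
        _inject(trace, FS, 10.0, 10.0)
        assert detect_events(Recording(FS, trace)) == []

    def test_threshold_below_noise_warns(self):
        rng = np.random.default_rng(0)
        rec = Recording(FS, rng.normal(0, 30.0, int(10 * FS)))
        with pytest.warns(UserWarning, match="noise floor"):
            detect_events(rec, DetectionParams(amplitude_threshold=5.0))

    def test_spike_like_flagging(self):
        trace = np.zeros(int(120 * FS))
        for t0 in np.arange(5.0, 110.0, 10.0):
            _inject(trace, FS, t0, 100.0)
        _inject(trace, FS, 115.0, 1000.0)
        events = detect_events(Recording(FS, trace))
        flags = [ev.is_spike_like for ev in events]
        assert sum(flags) == 1 and flags[-1]

    @pytest.mark.parametrize("seed", range(50))
    def test_count_recovery_property(self, seed):
        """All injected events are found when amplitudes are >= 2x threshold
        and gaps >= 2x the merge window."""
        rng = np.random.default_rng(seed)
        n_ev = int(rng.integers(3, 12))
        gaps = rng.uniform(0.05, 2.0, n_ev)  # >= 2 x 10 ms min gap + decay
        onsets = 1.0 + np.cumsum(gaps + 0.15)
        duration = onsets[-1] + 1.0
        trace = np.zeros(int(duration * FS))
        amps = rng.uniform(40.0, 400.0, n_ev)
        for t0, a in zip(onsets, amps):
            _inject(trace, FS, t0, a)
        trace += rng.normal(0, 5.0, len(trace))
        events = detect_events(Recording(FS, trace))
        assert len(events) == n_ev


class TestCharge:
    def test_rectangular_pulse(self):
        trace = np.zeros(int(60 * FS))
        trace[int(10 * FS) : int(11 * FS)] = -100.0
        rec = Recording(FS, trace)
        # 100 pA x 1 s = 100 pA·s = 0.1 nC (baseline window long enough
        # that the pulse cannot dominate the running median)
        assert charge_transferred(rec, baseline_window_s=10.0) == pytest.approx(0.1, rel=1e-3)

    def test_zero_trace(self):
        assert charge_transferred(Recording(FS, np.zeros(int(10 * FS)))) == 0.0

    def test_two_pulses_additive(self):
        one = np.zeros(int(60 * FS))
        one[int(10 * FS) : int(10.2 * FS)] = -50.0
        two = one.copy()
        two[int(40 * FS) : int(40.2 * FS)] = -50.0
        q1 = charge_transferred(Recording(FS, one))
        q2 = charge_transferred(Recording(FS, two))
        assert q2 == pytest.approx(2 * q1, abs=1e-9)

    def test_offset_invariance(self):
        rng = np.random.default_rng(1)
        trace = rng.normal(0, 5, int(60 * FS))
        _inject(trace, FS, 20.0, 300.0)
        q0 = charge_transferred(Recording(FS, trace))
        q1 = charge_transferred(Recording(FS, trace + 137.0))
        assert q1 == pytest.approx(q0, abs=1e-6)


class TestSummarize:
    def test_frequency(self):
        rec = Recording(FS, np.zeros(int(60 * FS)))
        events = [Event(t, t + 0.003, 100.0, 1.0) for t in np.linspace(1, 59, 30)]
        s = summarize(rec, events)
        assert s.frequency == pytest.approx(0.5)
        assert s.frequency * s.duration == pytest.approx(s.n_events)

    def test_mean_amplitude(self):
        rec = Recording(FS, np.zeros(int(10 * FS)))
        events = [Event(1.0, 1.01, 100.0, 1.0), Event(5.0, 5.01, 300.0, 1.0)]
        assert summarize(rec, events).mean_amplitude == pytest.approx(200.0)

    def test_empty_event_list(self):
        s = summarize(Recording(FS, np.zeros(int(10 * FS))), [])
        assert s.frequency == 0.0
        assert np.isnan(s.mean_amplitude)


class TestRecordingIO:
    def test_csv_roundtrip(self, tmp_path):
        rec, _ = sd.gen_recording(sd.get_psc_preset("control"), 5.0, 3)
        p = tmp_path / "trace.csv"
        write_recording(rec, p)
        back = read_recording(p)
        assert back.sampling_rate == pytest.approx(rec.sampling_rate, rel=1e-6)
        np.testing.assert_allclose(back.current, rec.current, atol=1e-3)

    def test_binary_roundtrip(self, tmp_path):
        rec, _ = sd.gen_recording(sd.get_psc_preset("control"), 5.0, 4)
        p = tmp_path / "trace.f32"
        write_recording(rec, p)
        back = read_recording(p)
        assert back.sampling_rate == rec.sampling_rate
        np.testing.assert_allclose(back.current, rec.current, atol=1e-3)
        assert back.condition_label == "control"


class TestCompareGroups:
    def test_identical_groups_not_significant(self):
        g = np.random.default_rng(0).normal(0, 1, 50)
        res = compare_groups({"a": g, "b": g.copy()})
        assert not res.significant
        assert res.p_value > 0.9

    def test_clear_separation_significant(self):
        rng = np.random.default_rng(3)
        res = compare_groups({"a": rng.normal(0, 1, 30), "b": rng.normal(5, 1, 30)})
        assert res.significant

    def test_two_group_nonnormal_uses_mannwhitney(self):
        rng = np.random.default_rng(5)
        a = rng.lognormal(0, 1.5, 40)  # heavily skewed
        b = rng.lognormal(0, 1.5, 40)
        res = compare_groups({"a": a, "b": b})
        assert res.test_name == "mann_whitney_u"

    def test_welch_dunnett_path_iff_levene_rejects(self):
        rng = np.random.default_rng(8)
        hetero = {f"g{i}": rng.normal(0, 1 + 2 * i, 12) for i in range(5)}
        res = compare_groups(hetero)
        assert res.levene_p < 0.05
        assert res.test_name == "welch_anova_dunnett_t3"
        assert len(res.posthoc) == 10
        homo = {f"g{i}": rng.normal(0, 1, 12) for i in range(5)}
        res2 = compare_groups(homo)
        assert res2.levene_p > 0.05
        assert res2.test_name == "one_way_anova_bonferroni"

    def test_small_group_is_usage_error(self):
        with pytest.raises(ValueError, match="n=2"):
            compare_groups({"a": np.arange(5.0), "b": np.array([1.0, 2.0])})

    def test_posthoc_flags_separated_group(self):
        rng = np.random.default_rng(9)
        groups = {
            "ctrl": rng.normal(0, 1, 15),
            "mid": rng.normal(0.2, 1.2, 15),
            "far": rng.normal(8, 5, 15),
        }
        res = compare_groups(groups)
        ph = res.posthoc
        far_rows = ph[(ph.group_a == "far") | (ph.group_b == "far")]
        assert far_rows["significant"].all()
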