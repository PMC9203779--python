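"""Pupillometry preprocessing: cleaning, epoching, peaks, gaze QC."""

import numpy as np
import pandas as pd
import pytest

from conftest import PHASES, fixed_rt_results, make_flat_profile

from incentive_ans.cohort import PupilStream, synthesize_pupil
from incentive_ans.pupil import (
    CleanTrace,
    average_eyes,
    baseline_correct,
    condition_average,
    deblink,
    epoch_phase,
    gaze_central_fraction,
    peak_pd,
    process_subject,
    smooth,
)


def stream_from_arrays(t_ms, left, right, events=None, fs=60.0, **gaze):
    n = len(t_ms)
    samples = pd.DataFrame(
        {
            "t_ms": t_ms,
            "left_mm": left,
            "right_mm": right,
            "gaze_x_deg": gaze.get("x", np.zeros(n)),
            "gaze_y_deg": gaze.get("y", np.zeros(n)),
            "event_label": gaze.get("label", np.full(n, "fixation", dtype=object)),
        }
    )
    if events is None:
        events = pd.DataFrame(
            [
                {
                    "trial": 0,
                    "incentive": "reward",
                    "correct": True,
                    "cue_onset_ms": 0.0,
                    "stimulus_onset_ms": 1500.0,
                    "response_ms": 2500.0,
                    "feedback_onset_ms": 2500.0,
                    "feedback_offset_ms": 4000.0,
                }
            ]
        )
    return PupilStream(sampling_rate_hz=fs, samples=samples, trial_events=events)


class TestAverageEyes:
    def test_samplewise_mean(self):
        s = stream_from_arrays([0.0, 16.7], [3.0, 3.0], [3.2, 3.2])
        tr = average_eyes(s)
        assert np.allclose(tr.diameter_mm, 3.1)

    def test_single_eye_fallback_and_double_missing(self):
        s = stream_from_arrays([0.0, 16.7], [np.nan, np.nan], [3.2, np.nan])
        tr = average_eyes(s)
        assert tr.diameter_mm[0] == 3.2
        assert np.isnan(tr.diameter_mm[1]) and not tr.valid[1]

    def test_averaging_halves_independent_noise(self):
        rng = np.random.default_rng(0)
        n = 20_000
        left = 4.0 + rng.normal(0, 0.1, n)
        right = 4.0 + rng.normal(0, 0.1, n)
        tr = average_eyes(stream_from_arrays(np.arange(n) * 16.7, left, right))
        assert tr.diameter_mm.var() == pytest.approx(0.1**2 / 2, rel=0.05)


class TestDeblink:
    def make_ramp_trace(self, gap_slice=None, fs=60.0, n=240):
        t = np.arange(n) * 1000.0 / fs
        y = 3.0 + 0.001 * t  # linear ramp
        valid = np.ones(n, dtype=bool)
        if gap_slice is not None:
            y = y.copy()
            y[gap_slice] = np.nan
            valid[gap_slice] = False
        return CleanTrace(t, y, valid, fs), pd.DataFrame(
            [
                {
                    "trial": 0,
                    "incentive": "reward",
                    "cue_onset_ms": 0.0,
                    "feedback_offset_ms": t[-1] + 1000.0 / fs,
                }
            ]
        )

    def test_small_gap_cubic_reproduces_ramp(self):
        tr, ev = self.make_ramp_trace(gap_slice=slice(100, 108))  # ~133 ms
        out = deblink(tr, ev, guard_ms=0.0)
        truth = 3.0 + 0.001 * tr.t_ms[100:108]
        assert np.allclose(out.diameter_mm[100:108], truth, atol=1e-9)
        assert out.trial_validity["valid"].all()

    def test_guard_margin_widens_gap(self):
        tr, ev = self.make_ramp_trace(gap_slice=slice(100, 104))
        out = deblink(tr, ev, guard_ms=50.0)  # 3 samples at 60 Hz
        # guarded neighbours are re-interpolated, still on the ramp
        truth = 3.0 + 0.001 * tr.t_ms
        assert np.allclose(out.diameter_mm, truth, atol=1e-9)

    def test_oversized_gap_left_missing(self):
        tr, ev = self.make_ramp_trace(gap_slice=slice(60, 110))  # ~833 ms
        out = deblink(tr, ev, max_blink_ms=500.0, guard_ms=0.0)
        assert np.isnan(out.diameter_mm[60:110]).all()

    def test_excessive_missing_trial_invalid(self):
        tr, ev = self.make_ramp_trace(gap_slice=slice(0, 150))  # 62% missing
        out = deblink(tr, ev, max_missing_frac=0.25)
        assert not out.trial_validity["valid"].iloc[0]
        assert out.trial_validity["missing_frac"].iloc[0] > 0.6

    def test_boundary_gap_cannot_interpolate(self):
        tr, ev = self.make_ramp_trace(gap_slice=slice(0, 6))
        out = deblink(tr, ev, guard_ms=0.0)
        assert np.isnan(out.diameter_mm[:6]).all()

    def test_discards_match_blink_schedule_oracle(self):
        """Pipeline trial discards equal brute-force enumeration from the
        generator's ground-truth blink schedule."""
        prof = make_flat_profile(blink_rate=0.35)
        stream = synthesize_pupil(prof, fixed_rt_results(40), seed=77)
        trace = deblink(average_eyes(stream), stream.trial_events)
        got = set(
            trace.trial_validity.loc[~trace.trial_validity["valid"], "trial"]
        )
        t = stream.samples["t_ms"].to_numpy()
        missing = np.zeros(t.size, dtype=bool)
        for b0, b1 in stream.blink_schedule:
            missing |= (t >= b0) & (t < b1)
        guard_n = int(round(40.0 / (1000.0 / 60.0)))
        guarded = missing.copy()
        for i in np.flatnonzero(missing):
            guarded[max(0, i - guard_n) : i + guard_n + 1] = True
        # undo the +1: expansion is over the run, equivalent per sample
        expected = set()
        for _, ev in stream.trial_events.iterrows():
            m = (t >= ev["cue_onset_ms"]) & (t < ev["feedback_offset_ms"])
            if guarded[m].mean() > 0.25:
                expected.add(int(ev["trial"]))
        assert got == expected


class TestSmooth:
    def make_trace(self, y, fs=60.0):
        y = np.asarray(y, dtype=float)
        return CleanTrace(np.arange(y.size) * 1000 / fs, y, np.isfinite(y), fs)

    def test_constant_preserved(self):
        out = smooth(self.make_trace(np.full(50, 3.3)))
        assert np.allclose(out.diameter_mm, 3.3)

    def test_impulse_becomes_plateau(self):
        y = np.zeros(21)
        y[10] = 1.0
        out = smooth(self.make_trace(y))
        assert np.allclose(out.diameter_mm[8:13], 0.2)
        assert np.allclose(out.diameter_mm[:8], 0.0)

    def test_edges_shrink_window(self):
        y = np.arange(10, dtype=float)
        out = smooth(self.make_trace(y))
        assert out.diameter_mm[0] == pytest.approx(np.mean(y[:3]))

    def test_noise_variance_reduced_fivefold(self):
        rng = np.random.default_rng(1)
        y = rng.normal(0, 1, 50_000)
        out = smooth(self.make_trace(y))
        assert out.diameter_mm[2:-2].var() == pytest.approx(1 / 5, rel=0.05)


class TestEpochs:
    def test_cue_epoch_window(self, clean_stream):
        trace = smooth(deblink(average_eyes(clean_stream), clean_stream.trial_events))
        epochs = epoch_phase(trace, clean_stream.trial_events, "cue")
        e = epochs[0]
        assert e.t_rel_ms[0] == pytest.approx(0.0, abs=1e-6)
        assert e.t_rel_ms[-1] < 1500.0
        assert len(e.trace) == round(1.5 * clean_stream.sampling_rate_hz)

    def test_stimulus_epoch_response_locked(self):
        """Response at 900 ms post-stimulus: window spans [-400, +1100] ms
        around stimulus onset (1500 ms ending 200 ms after the press)."""
        events = pd.DataFrame(
            [
                {
                    "trial": 0,
                    "incentive": "reward",
                    "correct": True,
                    "cue_onset_ms": 0.0,
                    "stimulus_onset_ms": 1500.0,
                    "response_ms": 2400.0,  # 900 ms RT
                    "feedback_onset_ms": 2400.0,
                    "feedback_offset_ms": 3900.0,
                }
            ]
        )
        n = 300
        t = np.arange(n) * 1000 / 60.0
        s = stream_from_arrays(t, np.full(n, 4.0), np.full(n, 4.0), events)
        trace = deblink(average_eyes(s), events)
        e = epoch_phase(trace, events, "stimulus")[0]
        start_rel_stim = (e.t_rel_ms[0] + 2400.0 + 200.0 - 1500.0) - 1500.0
        assert start_rel_stim == pytest.approx(-400.0, abs=1000 / 60)
        assert e.locking == "response_locked"

    def test_omission_skips_stimulus_epoch(self):
        events = pd.DataFrame(
            [
                {
                    "trial": 0,
                    "incentive": "control",
                    "correct": False,
                    "cue_onset_ms": 0.0,
                    "stimulus_onset_ms": 1500.0,
                    "response_ms": np.nan,
                    "feedback_onset_ms": 4500.0,
                    "feedback_offset_ms": 6000.0,
                }
            ]
        )
        n = 400
        t = np.arange(n) * 1000 / 60.0
        s = stream_from_arrays(t, np.full(n, 4.0), np.full(n, 4.0), events)
        trace = deblink(average_eyes(s), events)
        assert epoch_phase(trace, events, "stimulus") == []
        assert len(epoch_phase(trace, events, "cue")) == 1

    def test_back_to_back_trials_both_extracted(self, clean_stream):
        """No inter-trial interval: feedback epoch of trial k may overlap the
        next cue baseline, yet both epochs are extracted."""
        trace = deblink(average_eyes(clean_stream), clean_stream.trial_events)
        fb = epoch_phase(trace, clean_stream.trial_events, "feedback")
        cue = epoch_phase(trace, clean_stream.trial_events, "cue")
        assert len(fb) == len(clean_stream.trial_events)
        assert len(cue) == len(clean_stream.trial_events)


class TestBaseline:
    def test_constant_trace_zeroed(self):
        n = 300
        t = np.arange(n) * 1000 / 60.0
        s = stream_from_arrays(t, np.full(n, 3.5), np.full(n, 3.5))
        trace = deblink(average_eyes(s), s.trial_events)
        e = epoch_phase(trace, s.trial_events, "feedback")[0]
        ec = baseline_correct(e, trace, s.trial_events)
        assert np.allclose(ec.trace, 0.0)
        assert ec.baseline_mm == pytest.approx(3.5)

    def test_bump_recovered_exactly(self):
        n = 300
        t = np.arange(n) * 1000 / 60.0
        bump = 0.2 * np.exp(-((t - 3000) ** 2) / 2e5)
        s = stream_from_arrays(t, 3.0 + bump, 3.0 + bump)
        trace = deblink(average_eyes(s), s.trial_events)
        e = epoch_phase(trace, s.trial_events, "feedback")[0]
        ec = baseline_correct(e, trace, s.trial_events)
        # corrected trace = bump minus the bump's own baseline-window mean
        i0 = np.searchsorted(t, 2500.0 - 1e-9)
        expect = bump[i0 : i0 + len(ec.trace)] - (ec.baseline_mm - 3.0)
        assert np.allclose(ec.trace, expect, atol=1e-12)

    def test_pre_onset_mean_zero_property(self, clean_stream):
        """After correction, the 200 ms pre-onset window averages to 0."""
        trace = smooth(deblink(average_eyes(clean_stream), clean_stream.trial_events))
        for phase in PHASES:
            for e in epoch_phase(trace, clean_stream.trial_events, phase):
                ec = baseline_correct(e, trace, clean_stream.trial_events)
                if not ec.valid:
                    continue
                ev = clean_stream.trial_events.iloc[e.trial]
                onset = {
                    "cue": ev["cue_onset_ms"],
                    "feedback": ev["feedback_onset_ms"],
                    "stimulus": ev["response_ms"] + 200.0 - 1500.0,
                }[phase]
                t = trace.t_ms
                m = (t >= onset - 200.0) & (t < onset)
                assert (trace.diameter_mm[m] - ec.baseline_mm).mean() == pytest.approx(
                    0.0, abs=1e-12
                )


class TestAveragingAndPeaks:
    def make_epochs(self, n, trace):
        from incentive_ans.pupil import PupilEpoch

        return [
            PupilEpoch("cue", "stimulus_locked", i, "reward", np.arange(len(trace)), trace.copy())
            for i in range(n)
        ]

    def test_min_trials_rejection(self):
        assert condition_average(self.make_epochs(9, np.zeros(5))) is None

    def test_identical_epochs_mean(self):
        tr = np.array([0.1, 0.2, 0.3])
        curve, n = condition_average(self.make_epochs(10, tr))
        assert np.allclose(curve, tr) and n == 10

    def test_mean_within_3se_of_kernel(self):
        rng = np.random.default_rng(8)
        kernel = np.sin(np.linspace(0, np.pi, 90)) * 0.3
        sd = 0.05
        epochs = self.make_epochs(200, kernel)
        for e in epochs:
            e.trace = kernel + rng.normal(0, sd, kernel.size)
        curve, n = condition_average(epochs)
        se = sd / np.sqrt(200)
        assert np.all(np.abs(curve - kernel) < 3 * se + 1e-3)

    def test_peak_definitions(self):
        assert peak_pd(np.zeros(10), "cue") == 0.0
        curve = np.array([0.0, -0.1, 0.05, 0.2, 0.1])
        assert peak_pd(curve, "cue") == pytest.approx(0.3)
        assert peak_pd(curve, "feedback") == pytest.approx(0.2)
        assert peak_pd(curve, "stimulus") == pytest.approx(0.2)


class TestGaze:
    def test_all_central(self):
        n = 300
        t = np.arange(n) * 1000 / 60.0
        s = stream_from_arrays(t, np.full(n, 4.0), np.full(n, 4.0))
        per_trial, agg = gaze_central_fraction(s)
        assert (per_trial["pct_central"] == 100.0).all()

    def test_half_eccentric(self):
        n = 300
        t = np.arange(n) * 1000 / 60.0
        x = np.where(np.arange(n) % 2 == 0, 6.0, 1.0)  # alternate 6 and 1 deg
        s = stream_from_arrays(t, np.full(n, 4.0), np.full(n, 4.0), x=x)
        per_trial, _ = gaze_central_fraction(s)
        assert per_trial["pct_central"].iloc[0] == pytest.approx(50.0, abs=1.0)

    def test_blink_samples_excluded_from_denominator(self):
        n = 300
        t = np.arange(n) * 1000 / 60.0
        label = np.full(n, "fixation", dtype=object)
        label[::3] = "blink"
        x = np.zeros(n)
        x[::3] = 50.0  # far off-screen, but blink samples don't count
        s = stream_from_arrays(t, np.full(n, 4.0), np.full(n, 4.0), x=x, label=label)
        per_trial, _ = gaze_central_fraction(s)
        assert (per_trial["pct_central"] == 100.0).all()

    def test_matches_sample_counting_oracle(self):
        prof = make_flat_profile(blink_rate=0.2, dispersion=2.0)
        stream = synthesize_pupil(prof, fixed_rt_results(20), seed=42)
        per_trial, _ = gaze_central_fraction(stream)
        s = stream.samples
        windows = {
            "cue": ("cue_onset_ms", "stimulus_onset_ms"),
            "stimulus": ("stimulus_onset_ms", "feedback_onset_ms"),
            "feedback": ("feedback_onset_ms", "feedback_offset_ms"),
        }
        t = s["t_ms"].to_list()
        xs = s["gaze_x_deg"].to_list()
        ys = s["gaze_y_deg"].to_list()
        labels = s["event_label"].to_list()
        ev_by_trial = stream.trial_events.set_index("trial")
        for row in per_trial.itertuples():
            ev = ev_by_trial.loc[row.trial]
            c0, c1 = windows[row.phase]
            num = den = 0
            for ti, xi, yi, li in zip(t, xs, ys, labels):
                if ev[c0] <= ti < ev[c1] and li in ("fixation", "saccade"):
                    den += 1
                    if (xi**2 + yi**2) ** 0.5 < 5.0:
                        num += 1
            assert row.pct_central == pytest.approx(100.0 * num / den, abs=1e-9)


class TestEndToEnd:
    def test_reward_amplitude_monotonicity(self):
        """Raising only the generator's reward cue amplitude strictly raises
        the recovered reward-control cue peak difference."""
        diffs = []
        for amp in (0.15, 0.25, 0.35):
            prof = make_flat_profile(
                amps={
                    ("cue", "reward"): amp,
                    ("cue", "control"): 0.10,
                }
            )
            stream = synthesize_pupil(
                prof,
                fixed_rt_results(44),
                seed=3,
                noise_sd_mm=0.0,
                eye_noise_sd_mm=0.0,
                artifact_rate_hz=0.0,
            )
            out = process_subject("s", stream, min_trials=10)
            peaks = {
                (p.condition, p.phase): p.peak_pd_mm for p in out["peaks"]
            }
            diffs.append(peaks[("reward", "cue")] - peaks[("control", "cue")])
        assert diffs[0] < diffs[1] < diffs[2]

    def test_determinism_of_peak_table(self):
        prof = make_flat_profile(
            amps={("stimulus", "reward"): 0.3, ("stimulus", "control"): 0.2},
            blink_rate=0.2,
        )
        res = fixed_rt_results(30)
        outs = []
        for _ in range(2):
            stream = synthesize_pupil(prof, res, seed=13)
            outs.append(process_subject("s", stream, min_trials=5)["peaks"])
        assert outs[0] == outs[1]
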