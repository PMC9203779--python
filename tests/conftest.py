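import numpy as np
import pytest

from incentive_ans.cohort import SubjectProfile, synthesize_pupil
from incentive_ans.ez import EZParams, TrialResult

PHASES = ("cue", "stimulus", "feedback")
CONDS = ("reward", "control")


def make_flat_profile(amps=None, blink_rate=0.0, dispersion=0.5):
    """Profile with identical EZ params in both conditions and explicit
    phasic amplitudes (0 unless given)."""
    p = EZParams(v=0.2, a=0.1, t_ER=0.3)
    amp = {(ph, c): 0.0 for ph in PHASES for c in CONDS}
    if amps:
        amp.update(amps)
    return SubjectProfile(
        subject_id="s1",
        age_group="adolescents",
        ez_params={"reward": p, "control": p},
        tonic_pupil_mm=4.5,
        phasic_amplitudes_mm=amp,
        blink_rate_hz=blink_rate,
        gaze_dispersion_deg=dispersion,
    )


def fixed_rt_results(n_trials=24, rt_ms=1000.0):
    """Alternating reward/control trials with a fixed RT, all correct."""
    return [
        TrialResult(
            block_index=1,
            trial_index=i + 1,
            incentive="reward" if i % 2 == 0 else "control",
            rt_ms=rt_ms,
            correct=True,
        )
        for i in range(n_trials)
    ]


@pytest.fixture
def flat_profile():
    return make_flat_profile()


@pytest.fixture
def clean_stream():
    """Noise-free 60 Hz stream with no blinks: a deterministic baseline."""
    prof = make_flat_profile(
        amps={(ph, c): 0.2 for ph in PHASES for c in CONDS}
    )
    return synthesize_pupil(
        prof,
        fixed_rt_results(24),
        sampling_rate_hz=60.0,
        seed=5,
        noise_sd_mm=0.0,
        eye_noise_sd_mm=0.0,
        artifact_rate_hz=0.0,
    )
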