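import numpy as np
import pytest

from limbspeech.synth import (
    CouplingParams,
    StudyConfig,
    TrialSpec,
    simulate_biking_kinematics,
    simulate_ipu_plan,
    simulate_study,
)


@pytest.fixture(scope="session")
def leg_trial():
    """One clean 60 s legMot trial with its ground truth."""
    spec = TrialSpec(
        "P01", "female", 1, "legMot", duration=60.0,
        cycle_duration_mean=1.07, cycle_duration_sd=0.12, seed=42,
    )
    markers, gt = simulate_biking_kinematics(spec)
    return spec, markers, gt


@pytest.fixture(scope="session")
def noiseless_leg_trial():
    spec = TrialSpec(
        "P01", "female", 1, "legMot", duration=30.0,
        cycle_duration_mean=1.07, cycle_duration_sd=0.12, seed=7,
    )
    markers, gt = simulate_biking_kinematics(spec, noise_sd_cm=0.0)
    return spec, markers, gt


@pytest.fixture(scope="session")
def tiny_track_study():
    """4 participants x 3 conditions x 2 days, 40 s trials, track mode."""
    config = StudyConfig(
        n_participants=4, n_female=3, trial_duration=40.0,
        coupling=CouplingParams(), mode="tracks",
    )
    return simulate_study(config, seed=5)


@pytest.fixture(scope="session")
def speech_trial_audio():
    """Short armBlock trial with synthesized audio."""
    spec = TrialSpec("P01", "female", 1, "armBlock", duration=20.0, f0_baseline=210.0, seed=3)
    rng = spec.rng()
    ipus = simulate_ipu_plan(spec, rng)
    from limbspeech.synth import simulate_speech_audio

    audio, gt = simulate_speech_audio(
        spec, ipus, np.empty(0), np.empty(0), CouplingParams(), rng=rng
    )
    return spec, ipus, audio, gt
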