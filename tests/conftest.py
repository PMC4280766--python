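import hypothesis
import numpy as np
import pytest

from rehab_imu import (
    Dataset,
    Exercise,
    SensorSite,
    SITE_ORDER,
    SyntheticConfig,
    TrialLabel,
    TrialRecording,
    generate_cohort,
)
from rehab_imu.synthetic import (
    DEFAULT_AMPLITUDE_DEG,
    joint_trajectory,
    profile_to_channels,
)

hypothesis.settings.register_profile(
    "suite", derandomize=True, max_examples=25, deadline=None
)
hypothesis.settings.load_profile("suite")


def make_trial(
    subject: str,
    exercise: Exercise,
    rep: int,
    error=None,
    seed: int = 0,
    noise_sd_acc: float = 0.3,
    noise_sd_gyro: float = 1.5,
    amplitude_scale: float = 1.0,
    duration_s: float = 5.0,
) -> TrialRecording:
    """Build a single synthetic trial without going through a cohort."""
    rng = np.random.default_rng(seed)
    profile = joint_trajectory(
        exercise,
        amplitude_deg=DEFAULT_AMPLITUDE_DEG[exercise] * amplitude_scale,
        duration_s=duration_s,
        error=error,
    )
    sensors = {
        site: profile_to_channels(
            profile, site, noise_sd_acc=noise_sd_acc,
            noise_sd_gyro=noise_sd_gyro, rng=rng,
        )
        for site in SITE_ORDER
    }
    return TrialRecording(subject, exercise, rep, sensors)


def make_labelled_dataset(spec: list[tuple[str, Exercise, int, tuple | None]],
                          seed: int = 0) -> Dataset:
    """Dataset from (subject, exercise, rep, error-or-None) tuples."""
    trials = []
    for i, (subject, exercise, rep, error) in enumerate(spec):
        rec = make_trial(subject, exercise, rep, error=error, seed=seed + i)
        lab = TrialLabel(observed_errors=(error,) if error else ())
        trials.append((rec, lab))
    return Dataset(trials=trials)


@pytest.fixture(scope="session")
def small_cohort() -> Dataset:
    """4 subjects x 5 reps x 7 exercises with the default prevalence mix."""
    return generate_cohort(SyntheticConfig(n_subjects=4, reps_per_exercise=5, seed=11))


@pytest.fixture(scope="session")
def one_trial(small_cohort) -> TrialRecording:
    return small_cohort.trials[0][0]
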