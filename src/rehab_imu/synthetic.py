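"""Synthetic labelled IMU cohorts with the statistical structure the
analysis pipeline assumes.

No public recordings of the clinical exercise cohort exist, so this
module simulates it: per subject, per exercise, per repetition it draws
a performance class (correct, or one taxonomy error with a severity),
synthesises a smooth two-segment (thigh/shin) plus foot kinematic
profile for the repetition, and projects gravity through the resulting
orientation series to produce accelerometer channels, with angular
rates for the gyroscope and i.i.d. Gaussian sensor noise on every
channel.

The kinematics are deliberately simple — raised-cosine joint-angle
excursions from a posture-consistent rest position — which keeps every
generated trial analytically checkable (statics, rates, monotone error
magnitudes) while still expressing each error mode at the sensor site
where a physiotherapist would look for it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from typing import Mapping, Sequence

import numpy as np

from .data_model import (
    DEFAULT_SAMPLING_RATE_HZ,
    ERROR_TAXONOMY,
    EXERCISE_ORDER,
    GRAVITY_MS2,
    SITE_ORDER,
    ChannelBlock,
    Dataset,
    Exercise,
    Posture,
    SensorSite,
    TrialLabel,
    TrialRecording,
    validate_label_taxonomy,
)

#: Minimum per-trial sample count required downstream by the level-6
#: wavelet decomposition.
MIN_SAMPLES = 512

#: Nominal primary-movement amplitude per exercise (degrees).
DEFAULT_AMPLITUDE_DEG: dict[Exercise, float] = {
    Exercise.HEEL_SLIDE: 45.0,
    Exercise.HIP_ABDUCTION: 40.0,
    Exercise.HIP_EXTENSION: 25.0,
    Exercise.HIP_FLEXION: 60.0,
    Exercise.KNEE_EXTENSION: 70.0,
    Exercise.IRQ: 30.0,
    Exercise.SLR: 45.0,
}

# Rest pitch (deg) per site for each posture; values stay away from the
# +/-90 deg gimbal region of the accelerometer tilt formulas.
_REST_PITCH: dict[Posture, dict[SensorSite, float]] = {
    Posture.STANDING: {
        SensorSite.THIGH: -75.0, SensorSite.SHIN: -75.0, SensorSite.FOOT: 0.0,
    },
    Posture.SITTING: {
        SensorSite.THIGH: 0.0, SensorSite.SHIN: -75.0, SensorSite.FOOT: 0.0,
    },
    Posture.SUPINE: {
        SensorSite.THIGH: 0.0, SensorSite.SHIN: 0.0, SensorSite.FOOT: 75.0,
    },
}

# Primary excursion: (site, axis, coefficient on the exercise amplitude).
_PRIMARY: dict[Exercise, tuple[tuple[SensorSite, str, float], ...]] = {
    Exercise.HIP_FLEXION: (
        (SensorSite.THIGH, "pitch", 1.0),
        (SensorSite.SHIN, "pitch", 1.0),
        (SensorSite.FOOT, "pitch", 1.0),
    ),
    Exercise.HIP_EXTENSION: (
        (SensorSite.THIGH, "pitch", -1.0),
        (SensorSite.SHIN, "pitch", -1.0),
        (SensorSite.FOOT, "pitch", -1.0),
    ),
    Exercise.HIP_ABDUCTION: (
        (SensorSite.THIGH, "roll", 1.0),
        (SensorSite.SHIN, "roll", 1.0),
        (SensorSite.FOOT, "roll", 1.0),
    ),
    Exercise.KNEE_EXTENSION: (
        (SensorSite.SHIN, "pitch", 1.0),
        (SensorSite.FOOT, "pitch", 1.0),
    ),
    Exercise.HEEL_SLIDE: (
        (SensorSite.THIGH, "pitch", 0.9),
        (SensorSite.SHIN, "pitch", -0.6),
        (SensorSite.FOOT, "pitch", -0.6),
    ),
    Exercise.SLR: (
        (SensorSite.THIGH, "pitch", 1.0),
        (SensorSite.SHIN, "pitch", 1.0),
        (SensorSite.FOOT, "pitch", 1.0),
    ),
    Exercise.IRQ: (
        (SensorSite.THIGH, "pitch", 0.2),
        (SensorSite.SHIN, "pitch", 1.0),
        (SensorSite.FOOT, "pitch", 1.0),
    ),
}

# Full-severity (severity 10) magnitude of each error mode, degrees.
ERROR_GAIN_DEG: dict[str, float] = {
    "KneeFlx": 40.0,
    "HipFlx": 25.0,
    "HipER": 30.0,
    "HipAbd": 25.0,
    "HeelLifts": 20.0,
    "JerkyMovement": 5.0,
}

#: Heel-lift peak elevation at severity 10 (metres) for the foot-site
#: linear-acceleration component.
HEEL_LIFT_HEIGHT_M = 0.08


def uniform_severity() -> np.ndarray:
    """Uniform distribution over the 1-10 severity scale."""
    return np.full(10, 0.1)


def fixed_severity(severity: int) -> np.ndarray:
    """Point mass at one severity value (1-10)."""
    if not 1 <= severity <= 10:
        raise ValueError("severity must be in 1..10")
    p = np.zeros(10)
    p[severity - 1] = 1.0
    return p


def default_error_prevalence(
    exercises: Sequence[Exercise] = EXERCISE_ORDER,
    incorrect_fraction: float = 0.4,
) -> dict[tuple[Exercise, str], float]:
    """Unbalanced default: 60% correct, the remainder split evenly over
    the exercise's permitted error labels."""
    prev: dict[tuple[Exercise, str], float] = {}
    for ex in exercises:
        labels = ERROR_TAXONOMY[Exercise(ex)]
        for lbl in labels:
            prev[(Exercise(ex), lbl)] = incorrect_fraction / len(labels)
    return prev


@dataclasses.dataclass
class SyntheticConfig:
    """Full description of a synthetic cohort; the generated dataset is a
    pure function of this object (including ``seed``)."""

    n_subjects: int
    reps_per_exercise: int = 10
    sampling_rate: float = DEFAULT_SAMPLING_RATE_HZ
    rep_duration_s: float = 5.0
    exercises: tuple[Exercise, ...] = EXERCISE_ORDER
    error_prevalence: Mapping[tuple[Exercise, str], float] | None = None
    severity_distribution: np.ndarray = dataclasses.field(
        default_factory=uniform_severity
    )
    noise_sd_acc: float = 0.3       # m/s^2
    noise_sd_gyro: float = 1.5      # deg/s
    subject_variability: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        self.exercises = tuple(Exercise(e) for e in self.exercises)
        self.severity_distribution = np.asarray(
            self.severity_distribution, dtype=float
        )

    def resolved_prevalence(self) -> dict[tuple[Exercise, str], float]:
        if self.error_prevalence is None:
            return default_error_prevalence(self.exercises)
        return {
            (Exercise(ex), str(lbl)): float(p)
            for (ex, lbl), p in self.error_prevalence.items()
        }

    def validate(self) -> None:
        if self.n_subjects < 1 or self.reps_per_exercise < 1:
            raise ValueError("n_subjects and reps_per_exercise must be >= 1")
        if self.rep_duration_s * self.sampling_rate < MIN_SAMPLES:
            raise ValueError(
                f"rep_duration_s * sampling_rate must give >= {MIN_SAMPLES} "
                "samples (level-6 wavelet requirement)"
            )
        p = self.severity_distribution
        if p.shape != (10,) or np.any(p < 0) or not np.isclose(p.sum(), 1.0):
            raise ValueError(
                "severity_distribution must be 10 probabilities over 1..10"
            )
        prev = self.resolved_prevalence()
        per_ex: dict[Exercise, float] = {ex: 0.0 for ex in self.exercises}
        for (ex, lbl), prob in prev.items():
            if ex not in per_ex:
                continue
            if lbl not in ERROR_TAXONOMY[ex]:
                raise ValueError(
                    f"prevalence references label {lbl!r} outside the "
                    f"taxonomy of {ex.value}"
                )
            if not 0.0 <= prob <= 1.0:
                raise ValueError("prevalences must lie in [0, 1]")
            per_ex[ex] += prob
        for ex, total in per_ex.items():
            if total > 1.0 + 1e-12:
                raise ValueError(
                    f"error prevalences for {ex.value} sum to {total} > 1"
                )

    def config_hash(self) -> str:
        payload = dataclasses.asdict(self)
        payload["exercises"] = [e.value for e in self.exercises]
        payload["severity_distribution"] = self.severity_distribution.tolist()
        if self.error_prevalence is not None:
            payload["error_prevalence"] = sorted(
                (Exercise(ex).value, str(lbl), float(p))
                for (ex, lbl), p in self.error_prevalence.items()
            )
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclasses.dataclass
class SiteKinematics:
    """Orientation (deg) and extra linear acceleration (m/s^2, sensor
    z-axis aligned components stacked as columns x,y,z) of one site over
    one repetition."""

    pitch_deg: np.ndarray
    roll_deg: np.ndarray
    yaw_deg: np.ndarray
    lin_acc: np.ndarray  # (n, 3)


@dataclasses.dataclass
class KinematicProfile:
    """Per-site angle trajectories for one repetition."""

    sampling_rate: float
    sites: dict[SensorSite, SiteKinematics]

    @property
    def n_samples(self) -> int:
        return int(next(iter(self.sites.values())).pitch_deg.size)

    def returns_to_rest(self, tol_deg: float = 1.0) -> bool:
        """Angles at both ends of the repetition are within *tol_deg* of
        each other (the exercise starts and ends at its rest posture)."""
        for k in self.sites.values():
            for ang in (k.pitch_deg, k.roll_deg, k.yaw_deg):
                if abs(ang[0] - ang[-1]) > tol_deg:
                    return False
        return True


def _bump(t: np.ndarray, duration: float, amplitude: float) -> np.ndarray:
    """Raised-cosine excursion 0 -> amplitude -> 0 over [0, duration];
    C1-smooth against the constant rest posture at both ends."""
    return amplitude * 0.5 * (1.0 - np.cos(2.0 * np.pi * t / duration))


def _jerk_oscillation(t: np.ndarray, duration: float, amplitude: float) -> np.ndarray:
    """Band-limited (5 and 8 Hz) oscillation under a raised-cosine window
    so the profile still returns to rest."""
    window = 0.5 * (1.0 - np.cos(2.0 * np.pi * t / duration))
    mix = np.sin(2.0 * np.pi * 5.0 * t) + 0.6 * np.sin(2.0 * np.pi * 8.0 * t + 1.0)
    return amplitude * window * mix / 1.6


def joint_trajectory(
    exercise: Exercise,
    amplitude_deg: float,
    duration_s: float,
    error: tuple[str, int] | None = None,
    sampling_rate: float = DEFAULT_SAMPLING_RATE_HZ,
) -> KinematicProfile:
    """Smooth kinematic profile of one repetition, optionally with an
    injected error mode whose magnitude scales with severity/10.

    Error modes and the sites they touch:

    * ``KneeFlx`` — extra knee flexion: shin and foot pitch deviate from
      the thigh.
    * ``HipFlx`` — extra hip flexion: thigh pitch deviates.
    * ``HipAbd`` — extra hip abduction: whole-limb roll deviation.
    * ``HipER`` — external hip rotation: whole-limb yaw excursion with a
      smaller coupled roll component.
    * ``HeelLifts`` — foot pitch deviation plus a vertical foot
      acceleration transient from the heel elevation profile.
    * ``JerkyMovement`` — 4-10 Hz oscillation superposed on the primary
      movement angles.
    """
    exercise = Exercise(exercise)
    if amplitude_deg <= 0:
        raise ValueError("amplitude_deg must be positive")
    if error is not None:
        lbl, sev = error
        validate_label_taxonomy(exercise, TrialLabel(((lbl, sev),)))
    n = int(round(duration_s * sampling_rate))
    t = np.arange(n) / sampling_rate
    rest = _REST_PITCH[exercise.posture]
    sites = {
        site: SiteKinematics(
            pitch_deg=np.full(n, rest[site]),
            roll_deg=np.zeros(n),
            yaw_deg=np.zeros(n),
            lin_acc=np.zeros((n, 3)),
        )
        for site in SITE_ORDER
    }
    for site, axis, coeff in _PRIMARY[exercise]:
        arr = getattr(sites[site], f"{axis}_deg")
        arr += _bump(t, duration_s, coeff * amplitude_deg)

    if error is not None:
        lbl, sev = error
        m = sev / 10.0
        gain = ERROR_GAIN_DEG[lbl] * m
        if lbl == "KneeFlx":
            for site in (SensorSite.SHIN, SensorSite.FOOT):
                sites[site].pitch_deg -= _bump(t, duration_s, gain)
        elif lbl == "HipFlx":
            sites[SensorSite.THIGH].pitch_deg += _bump(t, duration_s, gain)
        elif lbl == "HipAbd":
            for site in SITE_ORDER:
                sites[site].roll_deg += _bump(t, duration_s, gain)
        elif lbl == "HipER":
            for site in SITE_ORDER:
                sites[site].yaw_deg += _bump(t, duration_s, gain)
                sites[site].roll_deg += _bump(t, duration_s, 0.3 * gain)
        elif lbl == "HeelLifts":
            sites[SensorSite.FOOT].pitch_deg += _bump(t, duration_s, gain)
            # vertical acceleration of the raised-cosine heel elevation
            omega = 2.0 * np.pi / duration_s
            h_acc = 0.5 * HEEL_LIFT_HEIGHT_M * m * omega**2 * np.cos(omega * t)
            sites[SensorSite.FOOT].lin_acc[:, 2] += h_acc
        elif lbl == "JerkyMovement":
            for site, axis, coeff in _PRIMARY[exercise]:
                arr = getattr(sites[site], f"{axis}_deg")
                arr += np.sign(coeff) * _jerk_oscillation(
                    t, duration_s, ERROR_GAIN_DEG[lbl] * m
                )
        else:  # pragma: no cover - taxonomy already validated
            raise ValueError(f"unknown error label {lbl!r}")

    return KinematicProfile(sampling_rate=sampling_rate, sites=sites)


def profile_to_channels(
    profile: KinematicProfile,
    site: SensorSite,
    noise_sd_acc: float = 0.0,
    noise_sd_gyro: float = 0.0,
    rng: np.random.Generator | None = None,
) -> ChannelBlock:
    """Project gravity through the site's orientation series and add the
    angular rates and sensor noise.

    With pitch ``p`` and roll ``r`` the noise-free accelerometer reads
    ``g * (sin p, cos p sin r, cos p cos r)`` so the tilt formulas in
    :mod:`rehab_imu.signals` invert it exactly; yaw (rotation about
    gravity) is invisible to the accelerometer and appears only in the
    gyroscope z channel.
    """
    if (noise_sd_acc > 0 or noise_sd_gyro > 0) and rng is None:
        raise ValueError("rng is required when noise is enabled")
    k = profile.sites[SensorSite(site)]
    p = np.deg2rad(k.pitch_deg)
    r = np.deg2rad(k.roll_deg)
    acc = np.column_stack(
        [
            GRAVITY_MS2 * np.sin(p),
            GRAVITY_MS2 * np.cos(p) * np.sin(r),
            GRAVITY_MS2 * np.cos(p) * np.cos(r),
        ]
    )
    acc += k.lin_acc
    dt = 1.0 / profile.sampling_rate
    gyro = np.column_stack(
        [
            np.gradient(k.roll_deg, dt),
            np.gradient(k.pitch_deg, dt),
            np.gradient(k.yaw_deg, dt),
        ]
    )
    if noise_sd_acc > 0:
        acc = acc + rng.normal(0.0, noise_sd_acc, acc.shape)
    if noise_sd_gyro > 0:
        gyro = gyro + rng.normal(0.0, noise_sd_gyro, gyro.shape)
    return ChannelBlock(
        acc[:, 0], acc[:, 1], acc[:, 2],
        gyro[:, 0], gyro[:, 1], gyro[:, 2],
        sampling_rate=profile.sampling_rate,
    )


def generate_cohort(config: SyntheticConfig) -> Dataset:
    """Generate a full labelled cohort; deterministic given the config."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    prev = config.resolved_prevalence()
    severities = np.arange(1, 11)
    trials: list[tuple[TrialRecording, TrialLabel]] = []
    for s in range(config.n_subjects):
        subject_id = f"S{s + 1:03d}"
        amp_scale = float(
            np.clip(1.0 + config.subject_variability * rng.standard_normal(),
                    0.6, 1.4)
        )
        # Duration variability only lengthens repetitions so the wavelet
        # minimum-length precondition can never be violated.
        dur_scale = 1.0 + abs(config.subject_variability * rng.standard_normal())
        for exercise in config.exercises:
            labels = ERROR_TAXONOMY[exercise]
            probs = np.array([prev.get((exercise, lbl), 0.0) for lbl in labels])
            for rep in range(1, config.reps_per_exercise + 1):
                u = rng.random()
                error: tuple[str, int] | None = None
                cum = 0.0
                for lbl, pr in zip(labels, probs):
                    cum += pr
                    if u < cum:
                        sev = int(
                            rng.choice(severities, p=config.severity_distribution)
                        )
                        error = (lbl, sev)
                        break
                amp = DEFAULT_AMPLITUDE_DEG[exercise] * amp_scale
                amp *= max(1.0 + 0.03 * rng.standard_normal(), 0.2)
                # snap the sample count to a multiple of 2^6 so the
                # level-6 periodized wavelet transform stays orthonormal
                n = config.rep_duration_s * dur_scale * config.sampling_rate
                n = max(int(round(n / 64.0)) * 64, MIN_SAMPLES)
                profile = joint_trajectory(
                    exercise,
                    amplitude_deg=amp,
                    duration_s=n / config.sampling_rate,
                    error=error,
                    sampling_rate=config.sampling_rate,
                )
                sensors = {
                    site: profile_to_channels(
                        profile, site,
                        noise_sd_acc=config.noise_sd_acc,
                        noise_sd_gyro=config.noise_sd_gyro,
                        rng=rng,
                    )
                    for site in SITE_ORDER
                }
                label = TrialLabel(
                    observed_errors=(error,) if error is not None else ()
                )
                trials.append(
                    (
                        TrialRecording(subject_id, exercise, rep, sensors),
                        label,
                    )
                )
    ds = Dataset(
        trials=trials,
        provenance=f"synthetic cohort (config hash {config.config_hash()})",
    )
    ds.validate()
    return ds
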