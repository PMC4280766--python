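"""Domain types, error taxonomy and the on-disk trial store.

The package analyses single repetitions ("trials") of seven lower-limb
rehabilitation exercises recorded by up to three body-worn inertial
measurement units placed on the thigh, shin and foot of the exercising
leg.  Each unit carries a tri-axial accelerometer (m/s^2) and a
tri-axial gyroscope (deg/s) sampled at 102.4 Hz.  A trial carries a
label: "correct", or one or more observed error modes, each with a
0-10 severity rating assigned by an observing physiotherapist.

Trials are stored on disk as one plain CSV per trial plus a JSON
manifest, so fixtures stay inspectable and diffable.
"""

from __future__ import annotations

import dataclasses
import enum
import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

GRAVITY_MS2 = 9.81
DEFAULT_SAMPLING_RATE_HZ = 102.4

CHANNEL_NAMES: tuple[str, ...] = (
    "acc_x", "acc_y", "acc_z", "gyro_x", "gyro_y", "gyro_z",
)


class SensorSite(str, enum.Enum):
    """Anatomical placement of one inertial sensor unit."""

    THIGH = "thigh"
    SHIN = "shin"
    FOOT = "foot"


#: Canonical site ordering used for feature-block concatenation.
SITE_ORDER: tuple[SensorSite, ...] = (
    SensorSite.THIGH, SensorSite.SHIN, SensorSite.FOOT,
)

#: The seven non-empty sensor subsets in the conventional reporting order.
SENSOR_COMBINATIONS: tuple[tuple[str, frozenset[SensorSite]], ...] = (
    ("foot", frozenset({SensorSite.FOOT})),
    ("shin", frozenset({SensorSite.SHIN})),
    ("thigh", frozenset({SensorSite.THIGH})),
    ("foot+shin", frozenset({SensorSite.FOOT, SensorSite.SHIN})),
    ("shin+thigh", frozenset({SensorSite.SHIN, SensorSite.THIGH})),
    ("thigh+foot", frozenset({SensorSite.THIGH, SensorSite.FOOT})),
    ("all", frozenset(SITE_ORDER)),
)


class Posture(str, enum.Enum):
    STANDING = "standing"
    SITTING = "sitting"
    SUPINE = "supine"


class Exercise(str, enum.Enum):
    """The seven lower-limb rehabilitation exercises under study."""

    HEEL_SLIDE = "heel_slide"
    HIP_ABDUCTION = "hip_abduction"
    HIP_EXTENSION = "hip_extension"
    HIP_FLEXION = "hip_flexion"
    KNEE_EXTENSION = "knee_extension"
    IRQ = "irq"
    SLR = "slr"

    @property
    def posture(self) -> Posture:
        return _POSTURE[self]


_POSTURE: dict[Exercise, Posture] = {
    Exercise.HEEL_SLIDE: Posture.SUPINE,
    Exercise.HIP_ABDUCTION: Posture.STANDING,
    Exercise.HIP_EXTENSION: Posture.STANDING,
    Exercise.HIP_FLEXION: Posture.STANDING,
    Exercise.KNEE_EXTENSION: Posture.SITTING,
    Exercise.IRQ: Posture.SUPINE,
    Exercise.SLR: Posture.SUPINE,
}

EXERCISE_ORDER: tuple[Exercise, ...] = tuple(Exercise)

#: Permitted error labels per exercise, in their canonical listing order
#: (the order is also the tie-break order when two observed errors share
#: the maximal severity).
ERROR_TAXONOMY: dict[Exercise, tuple[str, ...]] = {
    Exercise.HEEL_SLIDE: ("HeelLifts", "HipER", "JerkyMovement"),
    Exercise.HIP_ABDUCTION: ("HipER", "KneeFlx", "HipFlx"),
    Exercise.HIP_EXTENSION: ("HipER", "KneeFlx", "HipAbd"),
    Exercise.HIP_FLEXION: ("KneeFlx",),
    Exercise.KNEE_EXTENSION: ("HipFlx",),
    Exercise.IRQ: ("HipFlx", "HipER"),
    Exercise.SLR: ("KneeFlx",),
}

ALL_ERROR_LABELS: tuple[str, ...] = (
    "HeelLifts", "HipER", "JerkyMovement", "KneeFlx", "HipFlx", "HipAbd",
)


def is_binary_only(exercise: Exercise) -> bool:
    """True when only one error mode exists, so error identification
    collapses onto the correct/incorrect decision."""
    return len(ERROR_TAXONOMY[Exercise(exercise)]) == 1


@dataclasses.dataclass
class ChannelBlock:
    """Raw six-channel recording of one sensor unit for one trial.

    Accelerometer channels are in m/s^2, gyroscope channels in deg/s.
    """

    acc_x: np.ndarray
    acc_y: np.ndarray
    acc_z: np.ndarray
    gyro_x: np.ndarray
    gyro_y: np.ndarray
    gyro_z: np.ndarray
    sampling_rate: float = DEFAULT_SAMPLING_RATE_HZ

    def __post_init__(self) -> None:
        for name in CHANNEL_NAMES:
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        n = self.acc_x.size
        if n < 1:
            raise ValueError("channels must contain at least one sample")
        for name in CHANNEL_NAMES:
            if getattr(self, name).ndim != 1 or getattr(self, name).size != n:
                raise ValueError(
                    f"channel {name!r} length {getattr(self, name).size} "
                    f"differs from acc_x length {n}"
                )
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def n_samples(self) -> int:
        return int(self.acc_x.size)

    def channel(self, name: str) -> np.ndarray:
        if name not in CHANNEL_NAMES:
            raise KeyError(name)
        return getattr(self, name)

    def as_frame(self, prefix: str = "") -> pd.DataFrame:
        return pd.DataFrame(
            {f"{prefix}{name}": getattr(self, name) for name in CHANNEL_NAMES}
        )


@dataclasses.dataclass
class TrialRecording:
    """One repetition of one exercise by one subject."""

    subject_id: str
    exercise: Exercise
    repetition_index: int
    sensors: dict[SensorSite, ChannelBlock]

    def __post_init__(self) -> None:
        self.exercise = Exercise(self.exercise)
        self.sensors = {SensorSite(k): v for k, v in self.sensors.items()}
        if not self.sensors:
            raise ValueError("a trial needs at least one sensor block")
        if self.repetition_index < 1:
            raise ValueError("repetition_index starts at 1")
        blocks = list(self.sensors.values())
        n0, r0 = blocks[0].n_samples, blocks[0].sampling_rate
        for b in blocks[1:]:
            if b.n_samples != n0:
                raise ValueError(
                    f"trial {self.trial_id}: sensor blocks differ in length"
                )
            if b.sampling_rate != r0:
                raise ValueError(
                    f"trial {self.trial_id}: sensor blocks differ in sampling rate"
                )

    @property
    def trial_id(self) -> str:
        return f"{self.subject_id}:{self.exercise.value}:{self.repetition_index}"

    @property
    def sampling_rate(self) -> float:
        return next(iter(self.sensors.values())).sampling_rate

    @property
    def n_samples(self) -> int:
        return next(iter(self.sensors.values())).n_samples

    def sites(self) -> tuple[SensorSite, ...]:
        return tuple(s for s in SITE_ORDER if s in self.sensors)


@dataclasses.dataclass
class TrialLabel:
    """Observed performance label for one trial.

    ``observed_errors`` is empty for a correctly performed repetition;
    otherwise it lists ``(error_label, severity)`` pairs with severity on
    a ten-point scale.  ``classifiable`` is False for trials whose error
    cannot be seen by any lower-limb sensor (e.g. trunk movement) — such
    trials are removed during curation.  ``resolved_class`` is filled in
    by :func:`rehab_imu.evaluate.resolve_class`.
    """

    observed_errors: tuple[tuple[str, int], ...] = ()
    classifiable: bool = True
    resolved_class: str | None = None

    def __post_init__(self) -> None:
        self.observed_errors = tuple(
            (str(lbl), int(sev)) for lbl, sev in self.observed_errors
        )
        for lbl, sev in self.observed_errors:
            if not 0 <= sev <= 10:
                raise ValueError(f"severity {sev} for {lbl!r} outside 0-10")

    @property
    def is_correct(self) -> bool:
        return not self.observed_errors


def validate_label_taxonomy(exercise: Exercise, label: TrialLabel) -> None:
    """Raise if any observed error label is not permitted for *exercise*."""
    allowed = ERROR_TAXONOMY[Exercise(exercise)]
    for lbl, _ in label.observed_errors:
        if lbl not in allowed:
            raise ValueError(
                f"label {lbl!r} is not a permitted error for "
                f"{Exercise(exercise).value} (allowed: {', '.join(allowed)})"
            )


@dataclasses.dataclass
class Dataset:
    """A labelled collection of trials."""

    trials: list[tuple[TrialRecording, TrialLabel]]
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.trials)

    def validate(self) -> None:
        seen: set[str] = set()
        offenders: list[str] = []
        for rec, lab in self.trials:
            if rec.trial_id in seen:
                raise ValueError(f"duplicate trial id {rec.trial_id}")
            seen.add(rec.trial_id)
            try:
                validate_label_taxonomy(rec.exercise, lab)
            except ValueError:
                offenders.append(rec.trial_id)
        if offenders:
            raise ValueError(
                "trials with labels outside the exercise's error taxonomy: "
                + ", ".join(offenders)
            )

    def subjects(self) -> tuple[str, ...]:
        return tuple(sorted({rec.subject_id for rec, _ in self.trials}))


# ---------------------------------------------------------------------------
# On-disk store: one CSV per trial + JSON manifest
# ---------------------------------------------------------------------------

MANIFEST_NAME = "manifest.json"


def _trial_filename(rec: TrialRecording) -> str:
    return f"{rec.subject_id}_{rec.exercise.value}_rep{rec.repetition_index:02d}.csv"


def write_dataset(dataset: Dataset, path: str | Path) -> None:
    """Write *dataset* as one CSV per trial plus ``manifest.json``.

    CSV columns: ``sample_index`` (0-based) followed by six columns per
    present sensor, named ``<site>_<channel>`` with sites in thigh, shin,
    foot order.
    """
    dataset.validate()
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    entries = []
    rate: float | None = None
    for rec, lab in dataset.trials:
        rate = rec.sampling_rate if rate is None else rate
        if rec.sampling_rate != rate:
            raise ValueError("all trials in a store must share one sampling rate")
        fname = _trial_filename(rec)
        frames = [pd.DataFrame({"sample_index": np.arange(rec.n_samples)})]
        for site in rec.sites():
            frames.append(rec.sensors[site].as_frame(prefix=f"{site.value}_"))
        df = pd.concat(frames, axis=1)
        try:
            df.to_csv(path / fname, index=False, float_format="%.9g")
        except OSError as exc:  # pragma: no cover - environment dependent
            raise OSError(f"failed writing trial file {fname}: {exc}") from exc
        entries.append(
            {
                "subject": rec.subject_id,
                "exercise": rec.exercise.value,
                "repetition": rec.repetition_index,
                "file": fname,
                "errors": [
                    {"label": lbl, "severity": sev}
                    for lbl, sev in lab.observed_errors
                ],
                "classifiable": lab.classifiable,
            }
        )
    manifest = {
        "sampling_rate_hz": rate if rate is not None else DEFAULT_SAMPLING_RATE_HZ,
        "provenance": dataset.provenance,
        "trials": entries,
    }
    (path / MANIFEST_NAME).write_text(json.dumps(manifest, indent=1))


def read_dataset(path: str | Path) -> Dataset:
    """Read a store written by :func:`write_dataset` back into a Dataset."""
    path = Path(path)
    manifest_path = path / MANIFEST_NAME
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest found at {manifest_path}")
    manifest = json.loads(manifest_path.read_text())
    rate = float(manifest["sampling_rate_hz"])
    trials: list[tuple[TrialRecording, TrialLabel]] = []
    for entry in manifest["trials"]:
        fpath = path / entry["file"]
        if not fpath.exists():
            raise FileNotFoundError(
                f"manifest references missing trial file {fpath}"
            )
        df = pd.read_csv(fpath)
        sensors: dict[SensorSite, ChannelBlock] = {}
        for site in SITE_ORDER:
            cols = [f"{site.value}_{c}" for c in CHANNEL_NAMES]
            if all(c in df.columns for c in cols):
                sensors[site] = ChannelBlock(
                    *(df[c].to_numpy() for c in cols), sampling_rate=rate
                )
        rec = TrialRecording(
            subject_id=str(entry["subject"]),
            exercise=Exercise(entry["exercise"]),
            repetition_index=int(entry["repetition"]),
            sensors=sensors,
        )
        lab = TrialLabel(
            observed_errors=tuple(
                (e["label"], e["severity"]) for e in entry["errors"]
            ),
            classifiable=bool(entry.get("classifiable", True)),
        )
        trials.append((rec, lab))
    ds = Dataset(trials=trials, provenance=str(manifest.get("provenance", "")))
    ds.validate()
    return ds


# ---------------------------------------------------------------------------
# Trial accounting
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class ExclusionRecord:
    """Trials lost for a set of exercises: *n_subjects* affected subjects
    each losing *reps_lost* repetitions of every exercise in *exercises*."""

    exercises: frozenset[Exercise]
    n_subjects: int
    reps_lost: int


#: Cohort design the synthetic defaults emulate: 58 participants, 10
#: repetitions per exercise, with the recorded session losses (one
#: participant performed only the supine exercises, three could not
#: perform the SLR, and one heel-slide and one knee-extension session
#: were lost to sensor failure).
STUDY_ENROLLED = 58
STUDY_REPS_PER_EXERCISE = 10
STUDY_EXCLUSIONS: tuple[ExclusionRecord, ...] = (
    ExclusionRecord(
        frozenset(
            {
                Exercise.HIP_ABDUCTION,
                Exercise.HIP_FLEXION,
                Exercise.HIP_EXTENSION,
                Exercise.KNEE_EXTENSION,
            }
        ),
        n_subjects=1,
        reps_lost=10,
    ),
    ExclusionRecord(frozenset({Exercise.SLR}), n_subjects=3, reps_lost=10),
    ExclusionRecord(frozenset({Exercise.HEEL_SLIDE}), n_subjects=1, reps_lost=10),
    ExclusionRecord(frozenset({Exercise.KNEE_EXTENSION}), n_subjects=1, reps_lost=10),
)


def trial_accounting(
    enrolled: int,
    reps_per_exercise: int,
    exclusions: Sequence[ExclusionRecord] = (),
) -> dict[Exercise, int]:
    """Per-exercise trial counts from enrolment and exclusion records.

    Each exercise starts at ``enrolled * reps_per_exercise`` and loses
    ``n_subjects * reps_lost`` trials for every exclusion record that
    names it.
    """
    if enrolled < 0 or reps_per_exercise < 0:
        raise ValueError("counts must be non-negative")
    counts = {ex: enrolled * reps_per_exercise for ex in Exercise}
    for rec in exclusions:
        if rec.n_subjects < 0 or rec.reps_lost < 0:
            raise ValueError("exclusion counts must be non-negative")
        for ex in rec.exercises:
            ex = Exercise(ex)  # raises ValueError on unknown exercise
            counts[ex] -= rec.n_subjects * rec.reps_lost
    if any(v < 0 for v in counts.values()):
        raise ValueError("exclusions remove more trials than were recorded")
    return counts
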