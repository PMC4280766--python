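"""Label curation, leave-one-subject-out cross-validation, efficacy
metrics, and the sensor-subset ablation report.

Each trial's label record is resolved to a single class (the observed
error with the largest severity, or "correct"); unclassifiable trials
and classes with too few examples are excluded, with every exclusion
logged.  Classifiers are then trained and tested with leave-one-subject-
out cross-validation (LOSOCV): per fold, standardization, PCA and the
classifier are fit on all other subjects and the held-out subject's
trials are predicted, so evaluation is strictly subject-independent.
Results are summarised as accuracy / sensitivity / specificity per
exercise for each of the seven sensor-subset combinations, with an
unweighted cross-exercise average row rounded half-up for display.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .classify import (
    DEFAULT_RIDGE,
    DEFAULT_VARIANCE_THRESHOLD,
    fit_bank,
    fit_logistic,
    fit_projection,
    predict_proba,
    predict_multiclass,
    project,
)
from .data_model import (
    ERROR_TAXONOMY,
    EXERCISE_ORDER,
    SENSOR_COMBINATIONS,
    SITE_ORDER,
    Dataset,
    Exercise,
    SensorSite,
    TrialLabel,
    TrialRecording,
    is_binary_only,
)
from .features import dataset_features, feature_names

logger = logging.getLogger(__name__)

CORRECT = "correct"
INCORRECT = "incorrect"
DEFAULT_MIN_EXAMPLES = 40

MODES = ("binary", "multilabel")


def round_half_up(x: float) -> int:
    """Round to the nearest integer with halves going up (62.5 -> 63)."""
    return int(math.floor(x + 0.5))


def rounded_average(values: Iterable[float]) -> int:
    """Unweighted mean, rendered as an integer percent (half-up)."""
    vals = list(values)
    if not vals:
        raise ValueError("cannot average zero values")
    return round_half_up(float(np.mean(vals)))


def resolve_class(label: TrialLabel, exercise: Exercise) -> str | None:
    """Resolve a label record to one class, or None for removal.

    No observed errors -> "correct"; otherwise the error with the largest
    severity (ties broken by the exercise's taxonomy listing order).
    Unclassifiable trials resolve to None.
    """
    if not label.classifiable:
        return None
    if not label.observed_errors:
        return CORRECT
    order = ERROR_TAXONOMY[Exercise(exercise)]
    for lbl, _ in label.observed_errors:
        if lbl not in order:
            raise ValueError(
                f"error label {lbl!r} outside taxonomy of {exercise}"
            )
    # max severity; on ties the label listed first in the taxonomy wins
    best = max(label.observed_errors,
               key=lambda e: (e[1], -order.index(e[0])))
    return best[0]


@dataclasses.dataclass
class CuratedTrial:
    recording: TrialRecording
    cls: str

    @property
    def trial_id(self) -> str:
        return self.recording.trial_id


@dataclasses.dataclass
class CuratedDataset:
    """Trials with one resolved class each, plus the full exclusion log."""

    trials: list[CuratedTrial]
    exclusion_log: list[tuple[str, str]]
    class_counts: dict[tuple[Exercise, str], int]

    def __len__(self) -> int:
        return len(self.trials)

    def for_exercise(self, exercise: Exercise) -> list[CuratedTrial]:
        exercise = Exercise(exercise)
        return [t for t in self.trials if t.recording.exercise == exercise]

    def exercises(self) -> tuple[Exercise, ...]:
        present = {t.recording.exercise for t in self.trials}
        return tuple(e for e in EXERCISE_ORDER if e in present)

    def subjects(self) -> tuple[str, ...]:
        return tuple(sorted({t.recording.subject_id for t in self.trials}))


def curate(
    dataset: Dataset,
    min_examples: int = DEFAULT_MIN_EXAMPLES,
    classes: str = "resolved",
) -> CuratedDataset:
    """Resolve every trial to one class and drop what cannot be used.

    Removal reasons (each dropped trial appears once in the log):

    * ``unclassifiable`` — the label record is marked unclassifiable;
    * ``rare_label`` — the trial's class has fewer than *min_examples*
      examples for its exercise.

    ``classes`` selects the counting granularity for the rare-class rule:
    ``"resolved"`` counts each resolved class separately (the rule that
    protects the one-vs-all bank), ``"binary"`` counts the collapsed
    {correct, incorrect} classes (appropriate when only the binary
    decision will be evaluated, where the only "unseen deviation" risk is
    an entirely absent incorrect class).
    """
    if classes not in ("resolved", "binary"):
        raise ValueError("classes must be 'resolved' or 'binary'")
    resolved: list[tuple[TrialRecording, str]] = []
    log: list[tuple[str, str]] = []
    for rec, lab in dataset.trials:
        cls = resolve_class(lab, rec.exercise)
        if cls is None:
            log.append((rec.trial_id, "unclassifiable"))
        else:
            resolved.append((rec, cls))

    def counting_class(cls: str) -> str:
        if classes == "binary":
            return CORRECT if cls == CORRECT else INCORRECT
        return cls

    counts: dict[tuple[Exercise, str], int] = {}
    for rec, cls in resolved:
        key = (rec.exercise, counting_class(cls))
        counts[key] = counts.get(key, 0) + 1

    trials: list[CuratedTrial] = []
    kept_counts: dict[tuple[Exercise, str], int] = {}
    for rec, cls in resolved:
        if counts[(rec.exercise, counting_class(cls))] < min_examples:
            log.append((rec.trial_id, "rare_label"))
        else:
            trials.append(CuratedTrial(rec, cls))
            key = (rec.exercise, cls)
            kept_counts[key] = kept_counts.get(key, 0) + 1
    if not trials:
        raise ValueError("curation removed every trial")
    return CuratedDataset(trials=trials, exclusion_log=log,
                          class_counts=kept_counts)


# ---------------------------------------------------------------------------
# LOSOCV
# ---------------------------------------------------------------------------


def feature_table(
    curated: CuratedDataset,
    sites: Iterable[SensorSite] = SITE_ORDER,
    filter_first: bool = False,
) -> pd.DataFrame:
    """Feature table for curated trials (index: trial id; metadata columns
    subject, exercise, cls; then the named features)."""
    ds = Dataset(trials=[(t.recording, TrialLabel()) for t in curated.trials])
    df = dataset_features(ds, sites=sites, filter_first=filter_first)
    df.insert(2, "cls", [t.cls for t in curated.trials])
    return df


def _subset_columns(subset: Iterable[SensorSite]) -> list[str]:
    return list(feature_names(subset))


def losocv(
    curated: CuratedDataset,
    exercise: Exercise,
    subset: Iterable[SensorSite],
    mode: str = "binary",
    lam: float = DEFAULT_RIDGE,
    var_threshold: float = DEFAULT_VARIANCE_THRESHOLD,
    features: pd.DataFrame | None = None,
    filter_first: bool = False,
) -> pd.DataFrame:
    """Leave-one-subject-out predictions for one exercise and sensor
    subset.

    Per fold, the projection and classifier are fit on every other
    subject's trials and the held-out subject's trials are predicted.
    Folds whose training set loses a class entirely (or below 2 examples)
    are skipped with a logged warning and recorded in
    ``result.attrs["skipped_folds"]``.

    Returns a DataFrame with columns subject, truth, prediction indexed
    by trial id; in binary mode truths/predictions are
    "correct"/"incorrect".
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    exercise = Exercise(exercise)
    subset = {SensorSite(s) for s in subset}
    rows = curated.for_exercise(exercise)
    if not rows:
        raise ValueError(f"no curated trials for {exercise.value}")
    subjects = sorted({t.recording.subject_id for t in rows})
    if len(subjects) < 2:
        raise ValueError("LOSOCV needs at least 2 subjects")

    if features is None:
        sub_curated = CuratedDataset(rows, [], {})
        features = feature_table(sub_curated, sites=sorted(subset, key=SITE_ORDER.index),
                                 filter_first=filter_first)
    cols = _subset_columns(subset)
    missing = [c for c in cols if c not in features.columns]
    if missing:
        raise ValueError(f"feature table lacks columns for subset: {missing[:3]}")
    ids = [t.trial_id for t in rows]
    feats = features.loc[ids]
    X = feats[cols].to_numpy()
    y = np.array([t.cls for t in rows])
    subj = feats["subject"].to_numpy()
    if mode == "binary":
        y = np.where(y == CORRECT, CORRECT, INCORRECT)
    classes_all = sorted(set(y.tolist()))
    if mode == "multilabel" and len(classes_all) < 2:
        raise ValueError(
            f"multilabel evaluation of {exercise.value} needs >= 2 surviving "
            "classes"
        )
    if mode == "binary" and len(classes_all) < 2:
        raise ValueError(
            f"binary evaluation of {exercise.value} needs both correct and "
            "incorrect trials after curation"
        )

    out_idx: list[str] = []
    out_subj: list[str] = []
    out_truth: list[str] = []
    out_pred: list[str] = []
    skipped: list[str] = []
    for held_out in subjects:
        train = subj != held_out
        ytr = y[train]
        counts = {c: int(np.sum(ytr == c)) for c in classes_all}
        if any(n < 2 for n in counts.values()):
            lost = [c for c, n in counts.items() if n < 2]
            logger.warning(
                "skipping fold %s for %s (%s): training set lost class(es) %s",
                held_out, exercise.value, mode, lost,
            )
            skipped.append(held_out)
            continue
        proj = fit_projection(X[train], var_threshold=var_threshold)
        Ztr = project(proj, X[train])
        Zte = project(proj, X[~train])
        if mode == "binary":
            model = fit_logistic(Ztr, ytr == INCORRECT, lam=lam,
                                 positive_class=True)
            p = predict_proba(model, Zte)
            preds = np.where(p >= 0.5, INCORRECT, CORRECT)
        else:
            bank = fit_bank(Ztr, ytr, lam=lam)
            preds = np.array([predict_multiclass(bank, z) for z in Zte])
        test_ids = feats.index[~train]
        out_idx.extend(test_ids)
        out_subj.extend(subj[~train])
        out_truth.extend(y[~train])
        out_pred.extend(preds)
    result = pd.DataFrame(
        {"subject": out_subj, "truth": out_truth, "prediction": out_pred},
        index=out_idx,
    )
    result.attrs["skipped_folds"] = skipped
    result.attrs["exercise"] = exercise.value
    result.attrs["mode"] = mode
    return result


# ---------------------------------------------------------------------------
# Efficacy metrics
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class EfficacyScores:
    """Accuracy / sensitivity / specificity in percent, with the
    underlying confusion matrix (rows: truth, columns: prediction)."""

    accuracy: float
    sensitivity: float
    specificity: float
    confusion: pd.DataFrame

    def rounded(self) -> dict[str, int]:
        return {
            "accuracy": round_half_up(self.accuracy),
            "sensitivity": round_half_up(self.sensitivity),
            "specificity": round_half_up(self.specificity),
        }


def efficacy(
    predictions: Sequence, truths: Sequence, mode: str = "binary"
) -> EfficacyScores:
    """Efficacy scores from parallel prediction/truth sequences.

    Binary mode treats "incorrect" as the positive class: sensitivity is
    the detection rate of incorrectly performed repetitions.  Multilabel
    mode reports overall accuracy plus unweighted (macro) means of the
    per-class recalls and per-class true-negative rates; classes absent
    from the truths are excluded from the macro averages with a warning.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    pred = np.asarray(predictions)
    truth = np.asarray(truths)
    if pred.size == 0 or pred.size != truth.size:
        raise ValueError("predictions and truths must be equal-length, non-empty")
    n = pred.size
    confusion = pd.crosstab(
        pd.Series(truth, name="truth"), pd.Series(pred, name="prediction")
    )
    accuracy = 100.0 * float(np.sum(pred == truth)) / n
    if mode == "binary":
        tp = int(np.sum((truth == INCORRECT) & (pred == INCORRECT)))
        fn = int(np.sum((truth == INCORRECT) & (pred == CORRECT)))
        tn = int(np.sum((truth == CORRECT) & (pred == CORRECT)))
        fp = int(np.sum((truth == CORRECT) & (pred == INCORRECT)))
        if tp + fn == 0 or tn + fp == 0:
            logger.warning("one binary class absent from truths")
        sensitivity = 100.0 * tp / (tp + fn) if tp + fn else float("nan")
        specificity = 100.0 * tn / (tn + fp) if tn + fp else float("nan")
    else:
        truth_classes = sorted(set(truth.tolist()))
        extra = sorted(set(pred.tolist()) - set(truth_classes))
        if extra:
            logger.warning(
                "predicted classes absent from truths excluded from macro "
                "averages: %s", extra,
            )
        recalls = []
        tnrs = []
        for c in truth_classes:
            pos = truth == c
            recalls.append(float(np.sum(pred[pos] == c)) / np.sum(pos))
            neg = ~pos
            tnrs.append(float(np.sum(pred[neg] != c)) / np.sum(neg))
        sensitivity = 100.0 * float(np.mean(recalls))
        specificity = 100.0 * float(np.mean(tnrs))
    return EfficacyScores(
        accuracy=accuracy,
        sensitivity=sensitivity,
        specificity=specificity,
        confusion=confusion,
    )


# ---------------------------------------------------------------------------
# Ablation report
# ---------------------------------------------------------------------------

METRICS = ("sensitivity", "specificity", "accuracy")


@dataclasses.dataclass
class EfficacyReport:
    """Efficacy scores per (exercise, sensor combination, mode), plus the
    unweighted cross-exercise average per combination and mode."""

    scores: dict[tuple[Exercise, str, str], EfficacyScores]
    skipped_cells: list[tuple[str, str, str, str]]

    def combination_names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in SENSOR_COMBINATIONS)

    def exercises(self, mode: str) -> tuple[Exercise, ...]:
        present = {ex for (ex, _, m) in self.scores if m == mode}
        return tuple(e for e in EXERCISE_ORDER if e in present)

    def average(self, mode: str, combination: str, metric: str) -> float:
        vals = [
            getattr(self.scores[(ex, combination, mode)], metric)
            for ex in self.exercises(mode)
            if (ex, combination, mode) in self.scores
        ]
        if not vals:
            raise KeyError((mode, combination, metric))
        return float(np.mean(vals))

    def to_frame(self, mode: str) -> pd.DataFrame:
        """Table shaped like the published report: one row per
        (exercise, metric) plus an average block, columns = the seven
        sensor combinations, integer percent (half-up)."""
        combos = self.combination_names()
        rows = []
        index = []
        for ex in self.exercises(mode):
            for metric in METRICS:
                vals = []
                for combo in combos:
                    sc = self.scores.get((ex, combo, mode))
                    vals.append(
                        round_half_up(getattr(sc, metric))
                        if sc is not None else pd.NA
                    )
                rows.append(vals)
                index.append((ex.value, metric))
        for metric in METRICS:
            vals = []
            for combo in combos:
                try:
                    vals.append(round_half_up(self.average(mode, combo, metric)))
                except KeyError:
                    vals.append(pd.NA)
            rows.append(vals)
            index.append(("average", metric))
        return pd.DataFrame(
            rows,
            index=pd.MultiIndex.from_tuples(index, names=["exercise", "metric"]),
            columns=list(combos),
        )

    def to_json_dict(self) -> dict:
        out: dict = {"cells": [], "skipped": list(self.skipped_cells)}
        for (ex, combo, mode), sc in self.scores.items():
            out["cells"].append(
                {
                    "exercise": ex.value,
                    "sensors": combo,
                    "mode": mode,
                    "accuracy": sc.accuracy,
                    "sensitivity": sc.sensitivity,
                    "specificity": sc.specificity,
                    "confusion": {
                        str(t): {str(p): int(v) for p, v in row.items()}
                        for t, row in sc.confusion.iterrows()
                    },
                }
            )
        return out


def ablation_report(
    curated: CuratedDataset,
    modes: Sequence[str] = MODES,
    lam: float = DEFAULT_RIDGE,
    var_threshold: float = DEFAULT_VARIANCE_THRESHOLD,
    filter_first: bool = False,
) -> EfficacyReport:
    """LOSOCV efficacy for every exercise x 7 sensor combinations x
    applicable modes.

    Multilabel cells are omitted for exercises with a single permitted
    error (where the binary decision already identifies the error) and
    recorded as skipped when curation leaves fewer than 2 classes.
    Features are extracted once from all three sensors and sliced per
    combination.
    """
    full = feature_table(curated, sites=SITE_ORDER, filter_first=filter_first)
    scores: dict[tuple[Exercise, str, str], EfficacyScores] = {}
    skipped: list[tuple[str, str, str, str]] = []
    for ex in curated.exercises():
        feats_ex = full[full["exercise"] == ex.value]
        for mode in modes:
            if mode == "multilabel" and is_binary_only(ex):
                continue
            for combo_name, combo in SENSOR_COMBINATIONS:
                try:
                    preds = losocv(
                        curated, ex, combo, mode=mode, lam=lam,
                        var_threshold=var_threshold, features=feats_ex,
                    )
                except ValueError as exc:
                    logger.warning(
                        "skipping %s / %s / %s: %s",
                        ex.value, combo_name, mode, exc,
                    )
                    skipped.append((ex.value, combo_name, mode, str(exc)))
                    continue
                scores[(ex, combo_name, mode)] = efficacy(
                    preds["prediction"], preds["truth"], mode=mode
                )
    return EfficacyReport(scores=scores, skipped_cells=skipped)


def save_report(report: EfficacyReport, out_dir: str | Path,
                exclusion_log: Sequence[tuple[str, str]] = ()) -> None:
    """Write per-mode CSV tables plus a JSON with full-precision scores,
    confusion matrices and the exclusion log."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for mode in MODES:
        if report.exercises(mode):
            report.to_frame(mode).to_csv(out / f"{mode}.csv")
    payload = report.to_json_dict()
    payload["exclusion_log"] = [list(e) for e in exclusion_log]
    (out / "report.json").write_text(json.dumps(payload, indent=1))
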