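"""Per-trial feature extraction: 14 features x 9 signals = 126 per sensor.

Nine scalar statistics per signal (mean, population standard deviation,
moment skewness, Pearson kurtosis, energy, mean-level crossing rate,
range, 25th and 75th percentile) plus the variances of the detail
coefficients at levels 6..2 of a level-6 Daubechies-5 wavelet
decomposition under periodization.  Level-1 details (~25.6-51.2 Hz at a
102.4 Hz sampling rate) are omitted: that band is annihilated by the
20 Hz low-pass, which is what brings the per-signal count to 14 and the
per-sensor block to 126.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Iterable

import numpy as np
import pandas as pd
import pywt

from .data_model import (
    SITE_ORDER,
    Dataset,
    SensorSite,
    TrialRecording,
)
from .signals import SIGNAL_ORDER, derive_signal_set

SCALAR_FEATURES: tuple[str, ...] = (
    "mean", "std", "skewness", "kurtosis", "energy",
    "lcr", "range", "p25", "p75",
)
#: Wavelet detail-coefficient variances, coarsest level first.
WAVELET_FEATURES: tuple[str, ...] = ("wv_d6", "wv_d5", "wv_d4", "wv_d3", "wv_d2")
FEATURE_ORDER: tuple[str, ...] = SCALAR_FEATURES + WAVELET_FEATURES

FEATURES_PER_SENSOR = len(SIGNAL_ORDER) * len(FEATURE_ORDER)  # 126

WAVELET_NAME = "db5"
WAVELET_LEVEL = 6
MIN_WAVELET_SAMPLES = 512


def scalar_features(signal: np.ndarray) -> dict[str, float]:
    """The nine scalar statistics of one signal.

    Moments are population moments; skewness is m3/m2^1.5 and kurtosis
    is Pearson kurtosis m4/m2^2, both defined as 0 for a constant signal.
    The level crossing rate counts consecutive-sample pairs strictly
    straddling the signal mean, divided by N-1.
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("scalar features need a 1-D signal of length >= 2")
    m = float(x.mean())
    d = x - m
    m2 = float(np.mean(d**2))
    if m2 > 0.0:
        skew = float(np.mean(d**3)) / m2**1.5
        kurt = float(np.mean(d**4)) / m2**2
    else:
        skew = 0.0
        kurt = 0.0
    lcr = float(np.count_nonzero(d[:-1] * d[1:] < 0.0)) / (x.size - 1)
    p25, p75 = np.percentile(x, [25.0, 75.0])
    return {
        "mean": m,
        "std": float(np.sqrt(m2)),
        "skewness": skew,
        "kurtosis": kurt,
        "energy": float(np.sum(x**2)),
        "lcr": lcr,
        "range": float(x.max() - x.min()),
        "p25": float(p25),
        "p75": float(p75),
    }


def wavelet_decomposition(signal: np.ndarray) -> list[np.ndarray]:
    """Level-6 Daubechies-5 decomposition under periodization.

    Returns ``[cA6, cD6, cD5, cD4, cD3, cD2, cD1]``.  Periodization makes
    the transform orthonormal on dyadic lengths, so total coefficient
    energy equals signal energy (testable Parseval identity).
    """
    x = np.asarray(signal, dtype=float)
    if x.size < MIN_WAVELET_SAMPLES:
        raise ValueError(
            f"wavelet features need at least {MIN_WAVELET_SAMPLES} samples, "
            f"got {x.size}"
        )
    with warnings.catch_warnings():
        # pywt flags level 6 as deep for this length; periodization keeps
        # the transform well defined (and orthonormal on lengths divisible
        # by 2^6), so the warning is noise here.
        warnings.simplefilter("ignore", UserWarning)
        return pywt.wavedec(
            x, WAVELET_NAME, mode="periodization", level=WAVELET_LEVEL
        )


def wavelet_variances(signal: np.ndarray) -> dict[str, float]:
    """Population variances of the detail coefficients at levels 6..2
    (coarsest first)."""
    coeffs = wavelet_decomposition(signal)
    details = coeffs[1:6]  # cD6, cD5, cD4, cD3, cD2
    return {
        name: float(np.var(arr))
        for name, arr in zip(WAVELET_FEATURES, details)
    }


@dataclasses.dataclass
class FeatureVector:
    """Ordered, named feature values for one trial under a sensor subset.

    Names follow ``<site>.<signal>.<feature>`` with sites in thigh, shin,
    foot order, signals in :data:`rehab_imu.signals.SIGNAL_ORDER` and
    features in :data:`FEATURE_ORDER`; each present sensor contributes a
    block of exactly 126 values.
    """

    names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.names) != self.values.size:
            raise ValueError("names and values must align")
        if self.values.size % FEATURES_PER_SENSOR != 0:
            raise ValueError(
                f"length must be a multiple of {FEATURES_PER_SENSOR}"
            )

    def __len__(self) -> int:
        return int(self.values.size)

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(self.names))


def feature_names(sites: Iterable[SensorSite]) -> tuple[str, ...]:
    ordered = [s for s in SITE_ORDER if s in set(SensorSite(x) for x in sites)]
    return tuple(
        f"{site.value}.{sig}.{feat}"
        for site in ordered
        for sig in SIGNAL_ORDER
        for feat in FEATURE_ORDER
    )


def trial_features(
    trial: TrialRecording,
    subset: Iterable[SensorSite],
    filter_first: bool = False,
) -> FeatureVector:
    """Full feature vector of one trial for a chosen sensor subset."""
    subset = {SensorSite(s) for s in subset}
    missing = subset - set(trial.sensors)
    if missing:
        raise ValueError(
            f"trial {trial.trial_id} lacks requested sensors: "
            + ", ".join(s.value for s in sorted(missing, key=SITE_ORDER.index))
        )
    names: list[str] = []
    values: list[float] = []
    for site in SITE_ORDER:
        if site not in subset:
            continue
        sset = derive_signal_set(trial.sensors[site], filter_first=filter_first)
        for sig in SIGNAL_ORDER:
            x = sset[sig]
            feats = {**scalar_features(x), **wavelet_variances(x)}
            for feat in FEATURE_ORDER:
                names.append(f"{site.value}.{sig}.{feat}")
                values.append(feats[feat])
    arr = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(arr)):
        bad = [n for n, v in zip(names, arr) if not np.isfinite(v)]
        raise ValueError(
            f"non-finite feature values in trial {trial.trial_id}: {bad[:5]}"
        )
    return FeatureVector(tuple(names), arr)


def dataset_features(
    dataset: Dataset,
    sites: Iterable[SensorSite] = SITE_ORDER,
    filter_first: bool = False,
) -> pd.DataFrame:
    """Wide feature table: one row per trial, indexed by trial id, with
    subject/exercise/repetition metadata columns followed by the named
    features."""
    sites = tuple(SensorSite(s) for s in sites)
    rows = []
    index = []
    meta = {"subject": [], "exercise": [], "repetition": []}
    for rec, _lab in dataset.trials:
        fv = trial_features(rec, sites, filter_first=filter_first)
        rows.append(fv.values)
        index.append(rec.trial_id)
        meta["subject"].append(rec.subject_id)
        meta["exercise"].append(rec.exercise.value)
        meta["repetition"].append(rec.repetition_index)
    if not rows:
        raise ValueError("dataset contains no trials")
    names = feature_names(sites)
    df = pd.DataFrame(np.vstack(rows), columns=list(names), index=index)
    for k, v in reversed(meta.items()):
        df.insert(0, k, v)
    return df
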