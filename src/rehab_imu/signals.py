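"""Per-sensor signal derivation and low-pass filtering.

From the six raw channels of one sensor, three more analysis signals are
derived — overall acceleration magnitude, and the accelerometer tilt
angles pitch and roll — and all nine are low-pass filtered with a
4th-order Butterworth at 20 Hz, applied forward-backward (zero phase)
since the analysis is offline.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import signal as sps

from .data_model import ChannelBlock

#: Fixed signal ordering; feature naming and ordering depend on it.
SIGNAL_ORDER: tuple[str, ...] = (
    "acc_x", "acc_y", "acc_z",
    "gyro_x", "gyro_y", "gyro_z",
    "acc_magnitude", "pitch", "roll",
)

DEFAULT_CUTOFF_HZ = 20.0
DEFAULT_FILTER_ORDER = 4


def acceleration_magnitude(
    acc_x: np.ndarray, acc_y: np.ndarray, acc_z: np.ndarray
) -> np.ndarray:
    """Element-wise Euclidean norm of the accelerometer vector."""
    ax, ay, az = (np.asarray(a, dtype=float) for a in (acc_x, acc_y, acc_z))
    if not (ax.shape == ay.shape == az.shape):
        raise ValueError("accelerometer channels must have equal length")
    return np.sqrt(ax**2 + ay**2 + az**2)


def pitch_roll(
    acc_x: np.ndarray, acc_y: np.ndarray, acc_z: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Accelerometer-only tilt estimate, in degrees.

    pitch = atan2(ax, sqrt(ay^2 + az^2)) in [-90, 90];
    roll  = atan2(ay, az) in (-180, 180].

    Orientation is undefined where the acceleration vector vanishes;
    such samples raise.
    """
    ax, ay, az = (np.asarray(a, dtype=float) for a in (acc_x, acc_y, acc_z))
    if not (ax.shape == ay.shape == az.shape):
        raise ValueError("accelerometer channels must have equal length")
    norm = np.sqrt(ax**2 + ay**2 + az**2)
    if np.any(norm == 0.0):
        raise ValueError(
            "zero-norm accelerometer sample: tilt is undefined"
        )
    pitch = np.degrees(np.arctan2(ax, np.hypot(ay, az)))
    roll = np.degrees(np.arctan2(ay, az))
    return pitch, roll


def lowpass(
    x: np.ndarray,
    sampling_rate: float,
    order: int = DEFAULT_FILTER_ORDER,
    cutoff: float = DEFAULT_CUTOFF_HZ,
) -> np.ndarray:
    """Zero-phase Butterworth low-pass (forward-backward application).

    The two passes square the single-pass magnitude response; DC gain
    stays exactly 1.
    """
    x = np.asarray(x, dtype=float)
    nyquist = sampling_rate / 2.0
    if cutoff >= nyquist:
        raise ValueError(
            f"cutoff {cutoff} Hz must be below the Nyquist rate {nyquist} Hz"
        )
    b, a = sps.butter(order, cutoff / nyquist, btype="low")
    padlen = 3 * max(len(a), len(b))
    if x.size <= padlen:
        raise ValueError(
            f"signal too short for filter edge handling: need > {padlen} "
            f"samples, got {x.size}"
        )
    return sps.filtfilt(b, a, x)


@dataclasses.dataclass
class SignalSet:
    """The nine analysis signals of one sensor, in fixed order."""

    signals: dict[str, np.ndarray]
    sampling_rate: float

    def __post_init__(self) -> None:
        if tuple(self.signals.keys()) != SIGNAL_ORDER:
            raise ValueError("signals must carry exactly the nine names in order")
        n = next(iter(self.signals.values())).size
        if any(v.size != n for v in self.signals.values()):
            raise ValueError("all nine signals must have equal length")

    def __getitem__(self, name: str) -> np.ndarray:
        return self.signals[name]

    @property
    def names(self) -> tuple[str, ...]:
        return SIGNAL_ORDER

    @property
    def n_samples(self) -> int:
        return int(next(iter(self.signals.values())).size)


def derive_signal_set(
    block: ChannelBlock,
    filter_first: bool = False,
    order: int = DEFAULT_FILTER_ORDER,
    cutoff: float = DEFAULT_CUTOFF_HZ,
) -> SignalSet:
    """Compute the nine analysis signals for one sensor block.

    Default order of operations: derive magnitude/pitch/roll from the
    raw accelerometer, then low-pass all nine signals.  With
    ``filter_first=True`` the six raw channels are filtered before the
    derivation (and the derived signals are not filtered again).
    """
    raw = {name: block.channel(name) for name in
           ("acc_x", "acc_y", "acc_z", "gyro_x", "gyro_y", "gyro_z")}
    fs = block.sampling_rate

    def _derived(ax, ay, az):
        mag = acceleration_magnitude(ax, ay, az)
        pitch, roll = pitch_roll(ax, ay, az)
        return mag, pitch, roll

    if filter_first:
        filt = {k: lowpass(v, fs, order, cutoff) for k, v in raw.items()}
        mag, pitch, roll = _derived(filt["acc_x"], filt["acc_y"], filt["acc_z"])
        out = {**filt, "acc_magnitude": mag, "pitch": pitch, "roll": roll}
    else:
        mag, pitch, roll = _derived(raw["acc_x"], raw["acc_y"], raw["acc_z"])
        nine = {**raw, "acc_magnitude": mag, "pitch": pitch, "roll": roll}
        out = {k: lowpass(v, fs, order, cutoff) for k, v in nine.items()}

    return SignalSet(
        signals={name: out[name] for name in SIGNAL_ORDER}, sampling_rate=fs
    )
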