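"""Accelerometer recording I/O, preprocessing and windowing.

A smartphone's triaxial accelerometer mixes two components: a slowly varying
gravity vector and the linear acceleration imposed by the user's movement.
This module holds the containers for raw recordings and fixed-length signal
windows, reads and writes recordings as delimited text, and implements the
three preprocessing steps applied before feature extraction:

1. gravity removal by an exponential low-pass filter (subtracting the
   running weighted average from the raw signal),
2. noise reduction by a causal moving-average filter (default order 3),
3. segmentation into fixed-duration windows (default 3 s, i.e. 60 samples
   per axis at 20 Hz), the unit of feature extraction and classification.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .exceptions import DataError, FormatError, ParameterError

#: default logical-name -> column-header mapping for delimited recordings
DEFAULT_DIALECT: Mapping[str, str] = {
    "t": "t",
    "x": "x",
    "y": "y",
    "z": "z",
    "activity": "activity",
    "position": "position",
    "subject": "subject",
}

#: tolerated relative deviation of inter-sample spacing from 1/sampling_rate
_SPACING_TOL = 0.10


@dataclass
class AccelerometerRecording:
    """A timestamped triaxial acceleration signal with optional labels.

    Parameters
    ----------
    timestamps : array of seconds, strictly increasing, spacing within 10%
        of ``1/sampling_rate``.
    x, y, z : per-axis acceleration (device units, typically m/s^2).
    sampling_rate : nominal rate in Hz.
    activity_label, position_label, subject_id : optional metadata carried
        through preprocessing and into extracted features.
    """

    timestamps: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    sampling_rate: float
    activity_label: str | None = None
    position_label: str | None = None
    subject_id: str | None = None

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        n = self.timestamps.shape[0]
        for name in ("x", "y", "z"):
            if getattr(self, name).shape != (n,):
                raise DataError(
                    f"channel {name!r} length {getattr(self, name).shape} "
                    f"does not match {n} timestamps"
                )
        if not self.sampling_rate > 0:
            raise ParameterError(f"sampling_rate must be > 0, got {self.sampling_rate}")
        dt = np.diff(self.timestamps)
        if np.any(dt <= 0):
            raise DataError("timestamps must be strictly increasing")
        nominal = 1.0 / self.sampling_rate
        if dt.size and np.any(np.abs(dt - nominal) > _SPACING_TOL * nominal):
            raise DataError(
                "inter-sample spacing deviates more than "
                f"{_SPACING_TOL:.0%} from 1/sampling_rate = {nominal:g} s"
            )

    @property
    def n_samples(self) -> int:
        return self.timestamps.shape[0]

    @property
    def samples(self) -> np.ndarray:
        """The signal as an (N, 3) array in x, y, z column order."""
        return np.column_stack([self.x, self.y, self.z])

    def with_channels(self, channels: np.ndarray) -> "AccelerometerRecording":
        """Copy of this recording with channels replaced by an (N, 3) array."""
        return replace(
            self, x=channels[:, 0].copy(), y=channels[:, 1].copy(), z=channels[:, 2].copy()
        )


@dataclass
class SignalWindow:
    """A fixed-length 3-channel segment: the unit of feature extraction."""

    samples: np.ndarray  # (N, 3)
    sampling_rate: float
    window_seconds: float
    activity_label: str | None = None
    position_label: str | None = None
    subject_id: str | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        expected = int(round(self.window_seconds * self.sampling_rate))
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise DataError(f"window samples must be (N, 3), got {self.samples.shape}")
        if self.samples.shape[0] != expected:
            raise DataError(
                f"window has {self.samples.shape[0]} samples, expected "
                f"round({self.window_seconds} s x {self.sampling_rate} Hz) = {expected}"
            )
        if not np.all(np.isfinite(self.samples)):
            raise DataError("window contains non-finite samples")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    def axis(self, index: int) -> np.ndarray:
        return self.samples[:, index]


def read_recording(
    path,
    dialect: Mapping[str, str] | None = None,
    sampling_rate: float | None = None,
) -> AccelerometerRecording:
    """Read a delimited-text recording.

    When ``sampling_rate`` is not given it is inferred as the reciprocal of
    the median timestamp spacing. Label columns are optional; any mapped
    column that is absent is simply left unset.
    """
    cols = dict(DEFAULT_DIALECT)
    if dialect:
        cols.update(dialect)
    try:
        # round_trip parsing so write -> read is bit-exact
        frame = pd.read_csv(path, float_precision="round_trip")
    except (pd.errors.ParserError, UnicodeDecodeError) as exc:
        raise FormatError(f"could not parse {path}: {exc}") from exc
    missing = [cols[k] for k in ("t", "x", "y", "z") if cols[k] not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    if len(frame) < 2:
        raise FormatError(f"{path}: need at least 2 rows, found {len(frame)}")

    t = frame[cols["t"]].to_numpy(dtype=float)
    if sampling_rate is None:
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise DataError(f"{path}: timestamps are not strictly increasing")
        sampling_rate = 1.0 / float(np.median(dt))

    def _label(key: str) -> str | None:
        col = cols[key]
        if col in frame.columns:
            vals = frame[col].astype(str).unique()
            if len(vals) != 1:
                raise DataError(f"{path}: column {col!r} is not constant")
            return vals[0]
        return None

    return AccelerometerRecording(
        timestamps=t,
        x=frame[cols["x"]].to_numpy(dtype=float),
        y=frame[cols["y"]].to_numpy(dtype=float),
        z=frame[cols["z"]].to_numpy(dtype=float),
        sampling_rate=sampling_rate,
        activity_label=_label("activity"),
        position_label=_label("position"),
        subject_id=_label("subject"),
    )


def write_recording(
    rec: AccelerometerRecording, path, dialect: Mapping[str, str] | None = None
) -> None:
    """Write a recording as CSV (header + one row per sample).

    Label columns are emitted only when the corresponding field is set, so
    read -> write -> read round-trips every field exactly (floats are
    serialized with shortest round-trip repr).
    """
    cols = dict(DEFAULT_DIALECT)
    if dialect:
        cols.update(dialect)
    data: dict[str, Sequence] = {
        cols["t"]: rec.timestamps,
        cols["x"]: rec.x,
        cols["y"]: rec.y,
        cols["z"]: rec.z,
    }
    for key, value in (
        ("activity", rec.activity_label),
        ("position", rec.position_label),
        ("subject", rec.subject_id),
    ):
        if value is not None:
            data[cols[key]] = [value] * rec.n_samples
    try:
        # %.17g guarantees binary64 round-trip through text
        pd.DataFrame(data).to_csv(path, index=False, float_format="%.17g")
    except OSError as exc:
        raise OSError(f"cannot write recording to {path}: {exc}") from exc


def remove_gravity(rec: AccelerometerRecording, alpha: float = 0.8) -> AccelerometerRecording:
    """Subtract the exponentially smoothed gravity estimate from each channel.

    Per channel the gravity estimate follows
    ``g[n] = alpha * g[n-1] + (1 - alpha) * a[n]`` with ``g[0] = a[0]``; the
    output is ``a[n] - g[n]`` (linear acceleration). ``alpha`` close to 1
    tracks slowly (isolating gravity); ``alpha = 0`` tracks instantly and
    zeroes the signal.
    """
    if not 0.0 <= alpha < 1.0:
        raise ParameterError(f"alpha must be in [0, 1), got {alpha}")
    channels = rec.samples
    out = np.empty_like(channels)
    for j in range(3):
        a = channels[:, j]
        # IIR low-pass; zi = alpha*a[0] makes g[0] = (1-alpha)*a[0] + alpha*a[0] = a[0]
        g, _ = lfilter([1.0 - alpha], [1.0, -alpha], a, zi=np.array([alpha * a[0]]))
        out[:, j] = a - g
    return rec.with_channels(out)


def smooth(rec: AccelerometerRecording, order: int = 3) -> AccelerometerRecording:
    """Causal moving average: ``y[n] = mean(x[max(0, n-order+1) .. n])``.

    The first ``order - 1`` samples average the shorter available prefix
    (no padding), so output length equals input length and the output stays
    within the input's range.
    """
    if order < 1:
        raise ParameterError(f"order must be >= 1, got {order}")
    if order > rec.n_samples:
        raise ParameterError(
            f"order {order} exceeds signal length {rec.n_samples}"
        )
    if order == 1:
        return rec.with_channels(rec.samples)
    channels = rec.samples
    n = channels.shape[0]
    csum = np.vstack([np.zeros((1, 3)), np.cumsum(channels, axis=0)])
    idx = np.arange(n)
    lo = np.maximum(0, idx - order + 1)
    counts = (idx - lo + 1).astype(float)[:, None]
    out = (csum[idx + 1] - csum[lo]) / counts
    return rec.with_channels(out)


def segment(
    rec: AccelerometerRecording,
    window_seconds: float = 3.0,
    overlap_fraction: float = 0.0,
) -> list[SignalWindow]:
    """Cut a recording into fixed-length windows, inheriting its labels.

    Windows are non-overlapping by default; the hop is
    ``round(N_window * (1 - overlap_fraction))`` samples. A trailing partial
    window is discarded; a recording shorter than one window yields an empty
    list (not an error).
    """
    if not 0.0 <= overlap_fraction < 1.0:
        raise ParameterError(f"overlap_fraction must be in [0, 1), got {overlap_fraction}")
    if window_seconds <= 0:
        raise ParameterError(f"window_seconds must be > 0, got {window_seconds}")
    n_window = int(round(window_seconds * rec.sampling_rate))
    if n_window < 1:
        raise ParameterError("window shorter than one sample")
    step = max(1, int(round(n_window * (1.0 - overlap_fraction))))
    channels = rec.samples
    windows: list[SignalWindow] = []
    for start in range(0, rec.n_samples - n_window + 1, step):
        windows.append(
            SignalWindow(
                samples=channels[start : start + n_window].copy(),
                sampling_rate=rec.sampling_rate,
                window_seconds=window_seconds,
                activity_label=rec.activity_label,
                position_label=rec.position_label,
                subject_id=rec.subject_id,
            )
        )
    return windows
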