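"""Accelerometer and label I/O, resultant computation, and window segmentation.

The raw unit of data is a tri-axial accelerometer stream sampled at a fixed
rate (100 Hz by default) in units of g.  The Euclidean norm of the three axes
(the resultant, R) is carried as a fourth signal, and all downstream analysis
operates on non-overlapping fixed-length windows (10 s = 1000 samples at
100 Hz) of the four signals.

Label tracks are sequences of half-open intervals ``[start_s, end_s)`` each
carrying a 1-based activity class id, or the :data:`UNOBSERVED` sentinel for
stretches where no ground truth exists.  Windows are cut per labeled interval
(aligned to the interval start) so that a kept window never straddles an
activity transition; windows inside unobserved intervals are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: Sentinel class id for intervals with no ground-truth observation.
UNOBSERVED: int = -1

DEFAULT_SAMPLE_RATE_HZ: float = 100.0
DEFAULT_WINDOW_S: float = 10.0

ACCEL_COLUMNS = ("time_s", "x_g", "y_g", "z_g")
LABEL_COLUMNS = ("start_s", "end_s", "class_id")
DICTIONARY_COLUMNS = ("class_id", "name", "met", "intensity")


class ParseError(ValueError):
    """Raised when an input file is malformed; the message names the line."""


@dataclass
class AccelRecording:
    """A tri-axial accelerometer stream at a fixed sample rate, in g."""

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    sample_rate_hz: float = DEFAULT_SAMPLE_RATE_HZ
    start_time_s: float = 0.0

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        if not (len(self.x) == len(self.y) == len(self.z)):
            raise ValueError("x, y, z must have equal length")
        if len(self.x) == 0:
            raise ValueError("recording must be non-empty")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")

    def __len__(self) -> int:
        return len(self.x)

    @property
    def duration_s(self) -> float:
        return len(self) / self.sample_rate_hz

    @property
    def times_s(self) -> np.ndarray:
        return self.start_time_s + np.arange(len(self)) / self.sample_rate_hz


@dataclass
class LabelTrack:
    """Non-overlapping, sorted, half-open labeled intervals ``[start, end)``."""

    intervals: list[tuple[float, float, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ivs = [(float(s), float(e), int(c)) for s, e, c in self.intervals]
        for s, e, _ in ivs:
            if not s < e:
                raise ValueError(f"interval start {s} must precede end {e}")
        for (s0, e0, _), (s1, e1, _) in zip(ivs, ivs[1:]):
            if s1 < e0:
                raise ValueError("intervals must be sorted and non-overlapping")
        self.intervals = ivs

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)


@dataclass
class Window:
    """One fixed-length segment of the four signals; the unit of classification.

    ``samples`` has one column per signal in the order x, y, z, r.
    """

    index: int
    samples: np.ndarray
    class_id: int | None = None

    SIGNALS = ("x", "y", "z", "r")

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != 4:
            raise ValueError("samples must be an n x 4 matrix (x, y, z, r)")
        r = np.sqrt(np.sum(self.samples[:, :3] ** 2, axis=1))
        if not np.allclose(self.samples[:, 3], r, atol=1e-12, rtol=0.0):
            raise ValueError("column r must equal sqrt(x^2 + y^2 + z^2)")

    def signal(self, name: str) -> np.ndarray:
        return self.samples[:, self.SIGNALS.index(name)]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]


def compute_resultant(recording: AccelRecording) -> np.ndarray:
    """Element-wise Euclidean norm of the three axes (the R signal, in g)."""
    return np.sqrt(recording.x**2 + recording.y**2 + recording.z**2)


def segment_windows(
    recording: AccelRecording,
    labels: LabelTrack | None = None,
    window_s: float = DEFAULT_WINDOW_S,
) -> list[Window]:
    """Cut non-overlapping fixed-length windows from a recording.

    Without labels, windows tile the recording from its start and a trailing
    partial window is discarded.  With labels, windows tile each labeled
    interval from the interval's start, so no kept window crosses an activity
    transition; windows in :data:`UNOBSERVED` intervals and partial windows at
    interval edges are discarded.  Window indices count kept windows in
    temporal order.
    """
    n_win = window_s * recording.sample_rate_hz
    if abs(n_win - round(n_win)) > 1e-9:
        raise ValueError("window_s * sample_rate_hz must be an integer")
    n_win = int(round(n_win))
    if n_win <= 0:
        raise ValueError("window length must be positive")

    r = compute_resultant(recording)
    stacked = np.column_stack([recording.x, recording.y, recording.z, r])

    windows: list[Window] = []
    if labels is None:
        for i in range(len(recording) // n_win):
            seg = stacked[i * n_win : (i + 1) * n_win]
            windows.append(Window(index=len(windows), samples=seg, class_id=None))
        return windows

    for start_s, end_s, class_id in labels:
        if class_id == UNOBSERVED:
            continue
        i0 = int(round((start_s - recording.start_time_s) * recording.sample_rate_hz))
        i1 = int(round((end_s - recording.start_time_s) * recording.sample_rate_hz))
        i0 = max(i0, 0)
        i1 = min(i1, len(recording))
        for k in range((i1 - i0) // n_win):
            seg = stacked[i0 + k * n_win : i0 + (k + 1) * n_win]
            windows.append(Window(index=len(windows), samples=seg, class_id=class_id))
    return windows


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def read_accel_csv(path: str | Path) -> AccelRecording:
    """Read an accelerometer CSV with header ``time_s,x_g,y_g,z_g``.

    A leading comment line ``# sample_rate_hz=<rate>`` declares the sample
    rate; absent that, 100 Hz is assumed.  Time stamps must be monotone
    increasing.
    """
    path = Path(path)
    rate = DEFAULT_SAMPLE_RATE_HZ
    with open(path) as fh:
        first = fh.readline()
    skip = 0
    if first.startswith("#"):
        skip = 1
        if "sample_rate_hz=" in first:
            try:
                rate = float(first.split("sample_rate_hz=")[1].strip())
            except ValueError as exc:
                raise ParseError(f"{path}:1: bad sample_rate_hz header") from exc
    try:
        df = pd.read_csv(path, skiprows=skip, float_precision="round_trip")
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    missing = [c for c in ACCEL_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    if df[list(ACCEL_COLUMNS)].isna().any().any():
        bad = int(df[list(ACCEL_COLUMNS)].isna().any(axis=1).idxmax()) + 2 + skip
        raise ParseError(f"{path}:{bad}: malformed row")
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) == 0:
        raise ParseError(f"{path}: empty recording")
    if np.any(np.diff(t) <= 0):
        bad = int(np.argmax(np.diff(t) <= 0)) + 3 + skip
        raise ParseError(f"{path}:{bad}: time stamps not monotone increasing")
    return AccelRecording(
        x=df["x_g"].to_numpy(dtype=float),
        y=df["y_g"].to_numpy(dtype=float),
        z=df["z_g"].to_numpy(dtype=float),
        sample_rate_hz=rate,
        start_time_s=float(t[0]),
    )


def write_accel_csv(path: str | Path, recording: AccelRecording) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# sample_rate_hz={recording.sample_rate_hz:g}\n")
        fh.write(",".join(ACCEL_COLUMNS) + "\n")
        t = recording.times_s
        for i in range(len(recording)):
            fh.write(
                f"{t[i]:.4f},{recording.x[i]:.17g},"
                f"{recording.y[i]:.17g},{recording.z[i]:.17g}\n"
            )


def read_labels_csv(path: str | Path) -> LabelTrack:
    """Read a label CSV with header ``start_s,end_s,class_id``."""
    path = Path(path)
    try:
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    missing = [c for c in LABEL_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    intervals = []
    for i, row in df.iterrows():
        s, e, c = float(row["start_s"]), float(row["end_s"]), row["class_id"]
        if np.isnan(s) or np.isnan(e) or pd.isna(c):
            raise ParseError(f"{path}:{i + 2}: malformed row")
        if not s < e:
            raise ParseError(f"{path}:{i + 2}: end_s must exceed start_s")
        intervals.append((s, e, int(c)))
    try:
        return LabelTrack(intervals)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_labels_csv(path: str | Path, labels: LabelTrack) -> None:
    with open(path, "w") as fh:
        fh.write(",".join(LABEL_COLUMNS) + "\n")
        for s, e, c in labels:
            fh.write(f"{s:.4f},{e:.4f},{c}\n")


def read_activity_dictionary(path: str | Path) -> pd.DataFrame:
    """Read an activity dictionary CSV (``class_id,name,met,intensity``)."""
    df = pd.read_csv(path)
    missing = [c for c in DICTIONARY_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    return df.set_index("class_id", drop=False)


def write_activity_dictionary(path: str | Path, dictionary: pd.DataFrame) -> None:
    dictionary.to_csv(path, index=False, columns=list(DICTIONARY_COLUMNS))
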