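"""Core data model: recordings, labeled time windows, segments and feature tables.

Time is expressed in minutes relative to substance ingestion (t = 0 at
ingestion); a recording's ``time_origin`` is the time of its first sample on
that axis.  The default session runs from -25 to 200 minutes and is split into
three windows: the pre-effect control window (class 0) and two on-effect
windows (class 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class WindowSpec:
    """A labeled time interval, half-open in minutes: [start_min, end_min)."""

    window_id: int
    start_min: float
    end_min: float
    class_label: int

    def __post_init__(self) -> None:
        if not self.start_min < self.end_min:
            raise ValueError(
                f"window {self.window_id}: start {self.start_min} must precede end {self.end_min}"
            )
        if self.class_label not in (0, 1):
            raise ValueError(f"window {self.window_id}: class_label must be 0 or 1")

    @property
    def duration_min(self) -> float:
        return self.end_min - self.start_min


def default_windows() -> list[WindowSpec]:
    """The three standard session windows.

    Window 1 (-25 to 50 min around ingestion) is the control, class 0; windows
    2 (50-125 min) and 3 (125-200 min) are under the effect, class 1.  Total
    span: 225 minutes.
    """
    return [
        WindowSpec(1, -25.0, 50.0, 0),
        WindowSpec(2, 50.0, 125.0, 1),
        WindowSpec(3, 125.0, 200.0, 1),
    ]


def validate_windows(windows: list[WindowSpec]) -> None:
    """Check pairwise non-overlap and the control-window labeling convention."""
    ordered = sorted(windows, key=lambda w: w.start_min)
    for a, b in zip(ordered, ordered[1:]):
        if a.end_min > b.start_min + 1e-12:
            raise ValueError(f"windows {a.window_id} and {b.window_id} overlap")


@dataclass
class Recording:
    """One subject's multichannel signal.

    ``samples`` is channels x timepoints; row order follows ``channel_names``.
    """

    subject_id: str
    channel_names: list[str]
    sampling_rate: float
    samples: np.ndarray
    time_origin: float  # minutes of first sample relative to ingestion

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError(f"recording {self.subject_id}: duplicate channel names")
        if self.sampling_rate <= 0:
            raise ValueError(f"recording {self.subject_id}: sampling_rate must be > 0")
        if self.samples.ndim != 2 or self.samples.shape[0] != len(self.channel_names):
            raise ValueError(
                f"recording {self.subject_id}: samples must be (n_channels, n_timepoints); "
                f"got {self.samples.shape} for {len(self.channel_names)} channels"
            )

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_min(self) -> float:
        return self.n_samples / self.sampling_rate / 60.0

    def sample_index(self, t_min: float) -> int:
        """Index of the first sample at or after minute *t_min* (half-open grid)."""
        # ceil with a tiny slack so a sample nominally on the boundary lands
        # on the later window, never the earlier one
        return int(math.ceil((t_min - self.time_origin) * 60.0 * self.sampling_rate - 1e-9))


@dataclass
class Segment:
    """A recording restricted to one labeled window."""

    subject_id: str
    window_id: int
    class_label: int
    channel_names: list[str]
    sampling_rate: float
    samples: np.ndarray

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]


def split_windows(recording: Recording, windows: list[WindowSpec]) -> list[Segment]:
    """Cut a recording into one :class:`Segment` per window.

    Samples are assigned by the half-open convention [start, end): a sample
    falling exactly on a boundary belongs to the later window.  Raises if the
    recording does not span a window.
    """
    validate_windows(windows)
    segments: list[Segment] = []
    for w in windows:
        i0 = recording.sample_index(w.start_min)
        i1 = recording.sample_index(w.end_min)
        if i0 < 0 or i1 > recording.n_samples:
            raise ValueError(
                f"recording {recording.subject_id} (origin {recording.time_origin} min, "
                f"{recording.duration_min:.3f} min long) does not cover window "
                f"{w.window_id} [{w.start_min}, {w.end_min}) min"
            )
        segments.append(
            Segment(
                subject_id=recording.subject_id,
                window_id=w.window_id,
                class_label=w.class_label,
                channel_names=list(recording.channel_names),
                sampling_rate=recording.sampling_rate,
                samples=recording.samples[:, i0:i1],
            )
        )
    return segments


@dataclass
class FeatureTable:
    """Observations x features matrix with class labels and subject groups.

    ``level`` records the abstraction level: "A" (raw amplitudes), "B"
    (connectivity pairs) or "C" (graph measures).  ``groups`` carries the
    subject id of every row so splits can be made leakage-safe.
    """

    level: str
    feature_names: list[str]
    X: np.ndarray
    y: np.ndarray
    groups: np.ndarray
    window_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.int64)
        self.groups = np.asarray(self.groups)
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("feature names must be unique")
        if self.X.shape != (len(self.y), len(self.feature_names)):
            raise ValueError(
                f"X shape {self.X.shape} inconsistent with {len(self.y)} labels and "
                f"{len(self.feature_names)} features"
            )
        if len(self.groups) != len(self.y):
            raise ValueError("groups must align with rows")
        if not np.isfinite(self.X).all():
            raise ValueError("feature table contains non-finite values")
        if not np.isin(self.y, (0, 1)).all():
            raise ValueError("labels must be 0/1")

    @property
    def n_rows(self) -> int:
        return self.X.shape[0]

    def subset(self, mask: np.ndarray) -> "FeatureTable":
        return FeatureTable(
            level=self.level,
            feature_names=list(self.feature_names),
            X=self.X[mask],
            y=self.y[mask],
            groups=self.groups[mask],
            window_ids=None if self.window_ids is None else self.window_ids[mask],
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.feature_names)
        df.insert(0, "label", self.y)
        df.insert(1, "subject", self.groups)
        if self.window_ids is not None:
            df.insert(2, "window", self.window_ids)
        return df


def assemble_level_a(segments: list[Segment], decimate: int = 10) -> FeatureTable:
    """Stack windowed raw series into the level-A table (rows = timepoints).

    Each row is one timepoint, each column one channel; the row label is the
    class of the window the timepoint came from.  ``decimate`` keeps every
    k-th timepoint (stride) so synthetic runs stay desk-scale; use 1 to keep
    every sample.
    """
    if not segments:
        raise ValueError("no segments given")
    if decimate < 1:
        raise ValueError("decimate must be >= 1")
    montage = segments[0].channel_names
    for seg in segments:
        if seg.channel_names != montage:
            differing = sorted(set(seg.channel_names) ^ set(montage))
            raise ValueError(
                f"montage mismatch for subject {seg.subject_id} window {seg.window_id}: "
                f"differing channels {differing}"
            )
    blocks, labels, groups, window_ids = [], [], [], []
    for seg in segments:  # subject-major then time-major order
        block = seg.samples[:, ::decimate].T
        blocks.append(block)
        labels.append(np.full(block.shape[0], seg.class_label))
        groups.append(np.full(block.shape[0], seg.subject_id, dtype=object))
        window_ids.append(np.full(block.shape[0], seg.window_id))
    return FeatureTable(
        level="A",
        feature_names=list(montage),
        X=np.vstack(blocks),
        y=np.concatenate(labels),
        groups=np.concatenate(groups),
        window_ids=np.concatenate(window_ids),
    )
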