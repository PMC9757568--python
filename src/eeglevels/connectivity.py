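"""Pearson connectivity matrices (abstraction level B) and their flattening."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import FeatureTable, Segment


def pair_name(a: str, b: str, montage: list[str] | tuple[str, ...]) -> str:
    """Canonical feature name for a channel pair, montage order first."""
    ia, ib = list(montage).index(a), list(montage).index(b)
    if ia == ib:
        raise ValueError(f"pair requires two distinct channels, got {a!r} twice")
    if ia > ib:
        a, b = b, a
    return f"{a}-{b}"


@dataclass
class ConnectivityMatrix:
    """Symmetric Pearson correlation matrix for one subject-window."""

    subject_id: str
    window_id: int
    class_label: int
    channel_names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        n = len(self.channel_names)
        if self.values.shape != (n, n):
            raise ValueError(f"values must be {n}x{n}, got {self.values.shape}")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 1.0, atol=1e-12):
            raise ValueError("correlation matrix must have unit diagonal")
        if self.values.min() < -1 - 1e-12 or self.values.max() > 1 + 1e-12:
            raise ValueError("correlations must lie in [-1, 1]")

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)


def pearson_matrix(segment: Segment) -> ConnectivityMatrix:
    """Sample Pearson correlation of all channel pairs over the full segment."""
    X = segment.samples
    if X.shape[1] < 3:
        raise ValueError(
            f"subject {segment.subject_id} window {segment.window_id}: "
            f"need >= 3 timepoints, got {X.shape[1]}"
        )
    sd = X.std(axis=1)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        names = [segment.channel_names[i] for i in dead]
        raise ValueError(
            f"subject {segment.subject_id} window {segment.window_id}: "
            f"zero-variance channel(s) {names}; correlation undefined"
        )
    values = np.corrcoef(X)
    np.fill_diagonal(values, 1.0)
    values = np.clip((values + values.T) / 2.0, -1.0, 1.0)
    return ConnectivityMatrix(
        subject_id=segment.subject_id,
        window_id=segment.window_id,
        class_label=segment.class_label,
        channel_names=list(segment.channel_names),
        values=values,
    )


def pair_names(montage: list[str] | tuple[str, ...]) -> list[str]:
    """Names of the strictly-upper-triangle pairs in row-major order."""
    montage = list(montage)
    return [f"{montage[i]}-{montage[j]}"
            for i in range(len(montage)) for j in range(i + 1, len(montage))]


def flatten_connectivity(matrix: ConnectivityMatrix) -> tuple[list[str], np.ndarray]:
    """Strictly-upper-triangle entries in row-major order with pair names."""
    n = matrix.n_channels
    iu = np.triu_indices(n, k=1)
    return pair_names(matrix.channel_names), matrix.values[iu]


def unflatten_connectivity(vector: np.ndarray, channel_names: list[str]) -> np.ndarray:
    """Inverse of :func:`flatten_connectivity` (unit diagonal restored)."""
    n = len(channel_names)
    out = np.eye(n)
    iu = np.triu_indices(n, k=1)
    out[iu] = vector
    out[(iu[1], iu[0])] = vector
    return out


def epoch_segments(segments: list[Segment], epochs_per_window: int) -> list[Segment]:
    """Split each segment into contiguous equal sub-epochs (sample-size amplifier)."""
    if epochs_per_window < 1:
        raise ValueError("epochs_per_window must be >= 1")
    if epochs_per_window == 1:
        return list(segments)
    out = []
    for seg in segments:
        bounds = np.linspace(0, seg.n_samples, epochs_per_window + 1).astype(int)
        for e, (i0, i1) in enumerate(zip(bounds, bounds[1:])):
            out.append(Segment(
                subject_id=seg.subject_id,
                window_id=seg.window_id,
                class_label=seg.class_label,
                channel_names=list(seg.channel_names),
                sampling_rate=seg.sampling_rate,
                samples=seg.samples[:, i0:i1],
            ))
    return out


def connectivity_matrices(segments: list[Segment],
                          epochs_per_window: int = 1) -> list[ConnectivityMatrix]:
    """One Pearson matrix per (subject, window[, sub-epoch])."""
    return [pearson_matrix(seg) for seg in epoch_segments(segments, epochs_per_window)]


def assemble_level_b(matrices: list[ConnectivityMatrix]) -> FeatureTable:
    """Stack flattened connectivity matrices into the level-B feature table."""
    if not matrices:
        raise ValueError("no connectivity matrices given")
    montage = matrices[0].channel_names
    for m in matrices:
        if m.channel_names != montage:
            differing = sorted(set(m.channel_names) ^ set(montage))
            raise ValueError(
                f"montage mismatch for subject {m.subject_id} window {m.window_id}: "
                f"differing channels {differing}"
            )
    names = pair_names(montage)
    iu = np.triu_indices(len(montage), k=1)
    X = np.vstack([m.values[iu] for m in matrices])
    return FeatureTable(
        level="B",
        feature_names=names,
        X=X,
        y=np.array([m.class_label for m in matrices]),
        groups=np.array([m.subject_id for m in matrices], dtype=object),
        window_ids=np.array([m.window_id for m in matrices]),
    )


def write_connectivity_matrix(matrix: ConnectivityMatrix, path) -> None:
    """Square-matrix export: channel names as header row and column."""
    import pandas as pd

    pd.DataFrame(matrix.values, index=matrix.channel_names,
                 columns=matrix.channel_names).to_csv(path, float_format="%.17g")
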