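"""Synthetic multichannel cohorts with planted, fully known condition effects.

Signal model
------------
Each channel is a linear mixture of latent first-order autoregressive (AR(1))
sources plus white sensor noise.  Channels are grouped into *blocks*: channels
in the same block share a block source and therefore a controlled pairwise
correlation; channels in different blocks are uncorrelated at baseline.  The
condition (class 1) is expressed purely at the mixing level, which guarantees
that the implied channel correlation matrix is a Gram matrix and hence always
positive semi-definite:

* amplitude effects scale a channel's mixing row (and its noise) by a gain,
  leaving all correlations untouched;
* coupling effects blend a shared (or, for negative deltas, private) extra
  source into the two target channels, chosen so the *observed* channel
  correlation of the pair moves by exactly the requested delta;
* community effects reassign channels to a different block partition, so the
  latent community structure of the two conditions differs.

Because sensor noise attenuates correlations by 1/(1 + noise_sd**2), the
mixing coefficients are pre-compensated so that block correlations and
coupling deltas are exact at the observed-channel level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

from .connectivity import pair_name
from .data import Recording, WindowSpec, validate_windows
from .montage import MONTAGE_62


@dataclass
class EffectSpec:
    """Planted differences between the two conditions.

    amplitude_targets: (channel, gain) pairs; in class-1 windows the channel is
        scaled by the gain (gain >= 0).
    coupling_targets: ((channel_a, channel_b), delta) pairs; the observed
        Pearson correlation of the pair in class-1 windows exceeds the class-0
        value by exactly delta (population level).
    community_effect: optional (blocks_class0, blocks_class1), each a tuple of
        block sizes summing to the channel count.
    noise_sd: sensor noise standard deviation in signal units.
    """

    amplitude_targets: list[tuple[str, float]] = field(default_factory=list)
    coupling_targets: list[tuple[tuple[str, str], float]] = field(default_factory=list)
    community_effect: tuple[tuple[int, ...], tuple[int, ...]] | None = None
    noise_sd: float = 0.5

    def __post_init__(self) -> None:
        for name, gain in self.amplitude_targets:
            if gain < 0:
                raise ValueError(f"amplitude gain for {name} must be >= 0, got {gain}")
        for (a, b), delta in self.coupling_targets:
            if not -1.0 < delta < 1.0:
                raise ValueError(f"coupling delta for ({a}, {b}) must be in (-1, 1)")
        seen: set[str] = set()
        for (a, b), _ in self.coupling_targets:
            for ch in (a, b):
                if ch in seen:
                    raise ValueError(
                        f"channel {ch} appears in more than one coupling target; "
                        "each channel may be coupled at most once"
                    )
                seen.add(ch)
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def null_effect(noise_sd: float = 0.5) -> EffectSpec:
    """An effect spec with no planted difference between conditions."""
    return EffectSpec(noise_sd=noise_sd)


def _desk_windows() -> list[WindowSpec]:
    # one-minute windows mirroring the control / on-effect session structure
    return [WindowSpec(1, -1.0, 0.0, 0), WindowSpec(2, 0.0, 1.0, 1), WindowSpec(3, 1.0, 2.0, 1)]


@dataclass
class CohortSpec:
    """Full description of a synthetic cohort; identical specs give identical cohorts."""

    n_subjects: int = 16
    montage: tuple[str, ...] = MONTAGE_62
    sampling_rate: float = 100.0
    session_start: float = -1.0
    session_end: float = 2.0
    windows: list[WindowSpec] = field(default_factory=_desk_windows)
    effect: EffectSpec = field(default_factory=null_effect)
    ar_coefficient: float = 0.8
    n_latent_sources: int = 8
    within_block_corr: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if abs(self.ar_coefficient) >= 1:
            raise ValueError(
                f"ar_coefficient {self.ar_coefficient} is non-stationary (|phi| must be < 1)"
            )
        if not 1 <= self.n_latent_sources <= len(self.montage):
            raise ValueError("n_latent_sources must be in [1, n_channels]")
        validate_windows(self.windows)
        for w in self.windows:
            if w.start_min < self.session_start - 1e-12 or w.end_min > self.session_end + 1e-12:
                raise ValueError(f"session does not cover window {w.window_id}")
        names = set(self.montage)
        for name, _ in self.effect.amplitude_targets:
            if name not in names:
                raise ValueError(f"amplitude target {name!r} is not in the montage")
        for (a, b), _ in self.effect.coupling_targets:
            for ch in (a, b):
                if ch not in names:
                    raise ValueError(f"coupling target channel {ch!r} is not in the montage")
        if self.effect.community_effect is not None:
            for blocks in self.effect.community_effect:
                if sum(blocks) != len(self.montage):
                    raise ValueError(
                        f"community block sizes {blocks} must sum to {len(self.montage)} channels"
                    )

    @property
    def n_channels(self) -> int:
        return len(self.montage)

    @property
    def n_samples(self) -> int:
        return int(round((self.session_end - self.session_start) * 60.0 * self.sampling_rate))


def generate_sources(n_sources: int, n_samples: int, ar_coefficient: float,
                     seed: int | np.random.Generator) -> np.ndarray:
    """Mutually independent stationary AR(1) series with unit variance.

    x[t] = phi * x[t-1] + e[t], e ~ N(0, 1 - phi**2), x[0] drawn from the
    stationary distribution N(0, 1).  Returns (n_sources, n_samples).
    """
    if n_samples <= 0:
        raise ValueError("n_samples must be > 0")
    if abs(ar_coefficient) >= 1:
        raise ValueError(
            f"ar_coefficient {ar_coefficient} is non-stationary (|phi| must be < 1)"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    z = rng.standard_normal((n_sources, n_samples))
    innov_sd = np.sqrt(1.0 - ar_coefficient**2)
    e = z * innov_sd
    e[:, 0] = z[:, 0]  # stationary start: x[0] ~ N(0, 1)
    return lfilter([1.0], [1.0, -ar_coefficient], e, axis=1)


def _equal_blocks(n_channels: int, n_blocks: int) -> tuple[int, ...]:
    base, extra = divmod(n_channels, n_blocks)
    return tuple(base + (1 if i < extra else 0) for i in range(n_blocks))


def _block_of(blocks: tuple[int, ...]) -> np.ndarray:
    """Channel index -> block id for contiguous blocks of the given sizes."""
    return np.repeat(np.arange(len(blocks)), blocks)


class CouplingError(ValueError):
    """A coupling target implies a correlation structure that is not realizable."""


def _mixing_matrix(spec: CohortSpec, condition: int) -> np.ndarray:
    """Mixing matrix (channels x sources) for one condition.

    Source column layout: block sources, per-channel unique sources, two
    reserved columns per coupling target, per-channel sensor-noise columns.
    Rows have squared norm (1 + noise_sd**2) before amplitude gain, so
    channels are unit-variance signals plus noise.
    """
    n_ch = spec.n_channels
    sigma = spec.effect.noise_sd
    infl = 1.0 + sigma**2  # noise attenuation pre-compensation
    rho = spec.within_block_corr * infl
    if rho > 1.0:
        raise ValueError(
            f"within_block_corr {spec.within_block_corr} is not realizable with "
            f"noise_sd {sigma} (pre-compensated value {rho:.3f} > 1)"
        )
    if spec.effect.community_effect is not None:
        blocks = spec.effect.community_effect[condition]
    else:
        blocks = _equal_blocks(n_ch, spec.n_latent_sources)
    n_blocks = len(blocks)
    block_of = _block_of(blocks)

    n_pair_cols = 2 * len(spec.effect.coupling_targets)
    n_src = _n_source_rows(spec)
    M = np.zeros((n_ch, n_src))
    col_unique = n_blocks_max(spec)
    col_pairs = col_unique + n_ch
    col_noise = col_pairs + n_pair_cols

    M[np.arange(n_ch), block_of] = np.sqrt(rho)
    M[:, col_unique:col_unique + n_ch][np.diag_indices(n_ch)] = np.sqrt(1.0 - rho)

    montage = list(spec.montage)
    # channels receiving a positive coupling are detached from their block in
    # BOTH conditions, so the planted pair correlation is the sole systematic
    # class difference (no side effects on the channels' other correlations)
    for (a, b), delta in spec.effect.coupling_targets:
        if delta > 0:
            for idx in (montage.index(a), montage.index(b)):
                M[idx, :col_unique] = 0.0
                M[idx, col_unique + idx] = 1.0

    if condition == 1:
        for t, ((a, b), delta) in enumerate(spec.effect.coupling_targets):
            ia, ib = montage.index(a), montage.index(b)
            m0 = rho if (delta < 0 and block_of[ia] == block_of[ib]) else 0.0
            dtilde = delta * infl
            if dtilde > 0:
                lam = dtilde
                if lam > 1.0:
                    raise CouplingError(
                        f"coupling target ({a}, {b}, {delta:+}): implied correlation "
                        f"{dtilde / infl:.3f} exceeds 1 after noise compensation"
                    )
                for idx in (ia, ib):
                    M[idx, :col_pairs] *= np.sqrt(1.0 - lam)
                    M[idx, col_pairs + 2 * t] = np.sqrt(lam)
            elif dtilde < 0:
                if m0 <= 0 or dtilde < -m0:
                    raise CouplingError(
                        f"coupling target ({a}, {b}, {delta:+}): channels have baseline "
                        f"correlation {m0 / infl:.3f}; cannot lower it by {-delta:.3f}"
                    )
                mu = -dtilde / m0
                for k, idx in enumerate((ia, ib)):
                    M[idx, :col_pairs] *= np.sqrt(1.0 - mu)
                    M[idx, col_pairs + 2 * t + k] = np.sqrt(mu)
        for name, gain in spec.effect.amplitude_targets:
            M[montage.index(name), :] *= gain

    # sensor noise (scaled with any amplitude gain applied above via row scaling:
    # gains must also scale noise, so set noise after and rescale explicitly)
    noise_cols = M[:, col_noise:col_noise + n_ch]
    gains = np.ones(n_ch)
    if condition == 1:
        for name, gain in spec.effect.amplitude_targets:
            gains[montage.index(name)] = gain
    noise_cols[np.diag_indices(n_ch)] = sigma * gains
    return M


def n_blocks_max(spec: CohortSpec) -> int:
    if spec.effect.community_effect is not None:
        return max(len(b) for b in spec.effect.community_effect)
    return spec.n_latent_sources


def _n_source_rows(spec: CohortSpec) -> int:
    return n_blocks_max(spec) + 2 * spec.n_channels + 2 * len(spec.effect.coupling_targets)


def implied_correlation(spec: CohortSpec, condition: int) -> np.ndarray:
    """Population correlation matrix of the observed channels for one condition.

    Verified positive semi-definite (it is a normalized Gram matrix by
    construction, but the check is performed rather than assumed).
    """
    M = _mixing_matrix(spec, condition)
    C = M @ M.T
    d = np.sqrt(np.diag(C))
    corr = C / np.outer(d, d)
    eigmin = float(np.linalg.eigvalsh(corr).min())
    if eigmin < -1e-8:
        raise CouplingError(
            f"implied channel correlation matrix for condition {condition} is not "
            f"positive semi-definite (min eigenvalue {eigmin:.2e})"
        )
    return corr


def generate_cohort(spec: CohortSpec) -> list[Recording]:
    """Generate one recording per subject with the planted condition effects.

    The class-0 and class-1 stretches of a subject share the same latent
    source draw; only the mixing differs, so the planted effect is the sole
    systematic class difference.  Deterministic given the spec (incl. seed).
    """
    M0 = _mixing_matrix(spec, 0)
    M1 = _mixing_matrix(spec, 1)
    for condition in (0, 1):
        implied_correlation(spec, condition)  # realizability check

    n_ch = spec.n_channels
    n_src = _n_source_rows(spec)
    n_samples = spec.n_samples
    col_noise = n_src - n_ch

    # class-1 sample mask from the windows
    t_min = spec.session_start + np.arange(n_samples) / (spec.sampling_rate * 60.0)
    mask1 = np.zeros(n_samples, dtype=bool)
    for w in spec.windows:
        if w.class_label == 1:
            mask1 |= (t_min >= w.start_min - 1e-9) & (t_min < w.end_min - 1e-9)

    recordings = []
    child_seeds = np.random.SeedSequence(spec.seed).spawn(spec.n_subjects)
    for s, child in enumerate(child_seeds):
        rng = np.random.default_rng(child)
        S = generate_sources(col_noise, n_samples, spec.ar_coefficient, rng)
        W = rng.standard_normal((n_ch, n_samples))  # sensor noise, white
        sources = np.vstack([S, W])
        X = M0 @ sources
        if mask1.any():
            X[:, mask1] = M1 @ sources[:, mask1]
        recordings.append(Recording(
            subject_id=f"sub-{s + 1:02d}",
            channel_names=list(spec.montage),
            sampling_rate=spec.sampling_rate,
            samples=X,
            time_origin=spec.session_start,
        ))
    return recordings


def planted_truth(spec: CohortSpec) -> dict[str, list[str]]:
    """Ground-truth discriminative features per abstraction level.

    Level A: channels whose amplitude changes; level B: connectivity pairs
    whose correlation changes; level C: directional expectations on graph
    measures implied by the community effect.
    """
    truth_a = [name for name, gain in spec.effect.amplitude_targets if gain != 1.0]
    truth_b = [pair_name(a, b, spec.montage)
               for (a, b), delta in spec.effect.coupling_targets if delta != 0.0]
    truth_c: list[str] = []
    if spec.effect.community_effect is not None:
        blocks0, blocks1 = spec.effect.community_effect
        if len(blocks1) < len(blocks0):
            truth_c.append("community-APL measures increase")
        elif len(blocks1) > len(blocks0):
            truth_c.append("community-APL measures decrease")
    return {"A": truth_a, "B": truth_b, "C": truth_c}
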