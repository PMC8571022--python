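"""Synthetic resting-state EEG with known microstate structure.

The generator emulates the regime of a 64-channel, 5-minute, 1000 Hz
eyes-open resting recording: a hidden Markov-style sequence of K
quasi-stable scalp topographies, each visited for geometrically distributed
segments of a few tens of milliseconds, modulated by a rectified-sinusoid
amplitude envelope (GFP waxing and waning in the alpha band), with random
polarity inversions between segments and spatially white Gaussian sensor
noise. Every downstream stage can therefore be checked against exact ground
truth (templates, per-sample labels, segment table).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .containers import EEGRecording
from .montage import channel_positions, default_channels

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "make_template_maps",
    "sample_state_sequence",
    "synthesize_recording",
    "inject_artifacts",
    "simulate_subject",
]


def _default_transition_matrix(n_states: int) -> np.ndarray:
    """Uniform off-diagonal successor distribution (zero diagonal)."""
    if n_states == 1:
        return np.zeros((1, 1))
    T = np.full((n_states, n_states), 1.0 / (n_states - 1))
    np.fill_diagonal(T, 0.0)
    return T


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic-EEG generator.

    Defaults mirror the target data regime: 64 channels at 1000 Hz for
    300 s, four states with 80 ms mean segment duration, a 10 Hz (alpha)
    GFP envelope, free polarity inversion between segments, and sensor
    noise at 10% of the map norm.
    """

    n_channels: int = 64
    n_states: int = 4
    sampling_rate: float = 1000.0
    duration: float = 300.0
    mean_segment_duration: float | Sequence[float] = 80.0  # ms, scalar or per state
    transition_matrix: Optional[np.ndarray] = None
    envelope_freq: float = 10.0  # Hz
    polarity_flip_prob: float = 0.5  # per segment
    noise_sigma: float = 0.1  # noise SD / signal map L2 norm
    seed: int = 0

    def __post_init__(self) -> None:
        if self.transition_matrix is None:
            self.transition_matrix = _default_transition_matrix(self.n_states)
        self.transition_matrix = np.asarray(self.transition_matrix, dtype=float)
        T = self.transition_matrix
        if T.shape != (self.n_states, self.n_states):
            raise ValueError("transition_matrix must be n_states x n_states")
        if self.n_states > 1:
            if np.any(np.abs(T.sum(axis=1) - 1.0) > 1e-12):
                raise ValueError("transition_matrix rows must sum to 1")
        if np.any(np.diag(T) != 0.0):
            raise ValueError("transition_matrix diagonal must be exactly 0")
        if np.any(self.mean_durations_ms <= 0):
            raise ValueError("mean_segment_duration must be positive")
        if self.duration <= 0 or self.sampling_rate <= 0:
            raise ValueError("duration and sampling_rate must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")

    @property
    def mean_durations_ms(self) -> np.ndarray:
        """Per-state mean segment duration in ms (broadcast from scalar)."""
        m = np.asarray(self.mean_segment_duration, dtype=float)
        if m.ndim == 0:
            m = np.full(self.n_states, float(m))
        if m.shape != (self.n_states,):
            raise ValueError("mean_segment_duration must be scalar or length n_states")
        return m

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.sampling_rate))


@dataclass
class GroundTruth:
    """Everything the generator knows that an analyst must recover."""

    templates: np.ndarray  # (n_states, n_channels), unit-norm, avg-referenced
    label_sequence: np.ndarray  # (n_samples,) int
    segment_table: list[tuple[int, int, int, int]]  # (state, start, end, polarity)

    def __post_init__(self) -> None:
        total = 0
        prev_end = 0
        for _, start, end, _ in self.segment_table:
            if start != prev_end:
                raise ValueError("segments must tile the sequence without gaps")
            prev_end = end
            total = end
        if total != len(self.label_sequence):
            raise ValueError("segments must cover the full label sequence")


def _smooth_random_map(positions: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """A random smooth potential field on the electrode sphere.

    Mixture of a random linear gradient (dipole-like) and 1-3 von
    Mises-Fisher bumps; smoothness makes neighbouring electrodes correlate,
    as genuine scalp fields do.
    """
    n = positions.shape[0]
    u = rng.normal(size=3)
    u /= np.linalg.norm(u)
    f = positions @ u
    for _ in range(rng.integers(1, 4)):
        c = rng.normal(size=3)
        c /= np.linalg.norm(c)
        kappa = rng.uniform(2.0, 6.0)
        amp = rng.uniform(-1.0, 1.0)
        f = f + amp * np.exp(kappa * (positions @ c - 1.0))
    f = f - f.mean()
    norm = np.linalg.norm(f)
    if norm < 1e-12:  # pathological draw; caller resamples
        return np.zeros(n)
    return f / norm


def make_template_maps(
    n_channels: int,
    n_states: int,
    seed: int = 0,
    min_separation: float = 0.3,
    positions: Optional[np.ndarray] = None,
    max_attempts: int = 500,
) -> np.ndarray:
    """Draw ``n_states`` smooth, mutually distinct template topographies.

    Each map is average-referenced and unit L2 norm; every pair satisfies
    |spatial correlation| <= 1 - min_separation. For multi-state sets the
    draw additionally enforces scalp coverage — every electrode's RMS
    amplitude across the set is at least 60% of the median electrode's —
    because the classic microstate classes jointly activate the whole
    scalp; sets violating this (an electrode silent in *all* states) are
    unrealistic and are resampled.

    Raises
    ------
    RuntimeError
        If the constraints cannot be met within ``max_attempts``
        resampling attempts.
    """
    if n_states > n_channels:
        raise ValueError("n_states must not exceed n_channels")
    if not 0 <= min_separation < 1:
        raise ValueError("min_separation must be in [0, 1)")
    if positions is None:
        positions = channel_positions(default_channels(n_channels))
    rng = np.random.default_rng(seed)
    attempts = 0
    while attempts < max_attempts:
        maps: list[np.ndarray] = []
        while len(maps) < n_states and attempts < max_attempts:
            attempts += 1
            cand = _smooth_random_map(positions, rng)
            if np.linalg.norm(cand) < 0.5:
                continue
            if all(
                abs(float(cand @ m)) <= 1.0 - min_separation for m in maps
            ):
                maps.append(cand)
        if len(maps) < n_states:
            break
        M = np.array(maps)
        if n_states == 1:
            return M
        rms = np.sqrt((M**2).mean(axis=0))
        if rms.min() >= 0.6 * np.median(rms):
            return M
    raise RuntimeError(
        f"could not draw {n_states} maps with min_separation="
        f"{min_separation} in {max_attempts} attempts"
    )


def sample_state_sequence(config: GeneratorConfig) -> GroundTruth:
    """Sample the hidden label sequence (no EEG yet).

    Segment lengths are geometric at sample resolution with the configured
    per-state mean; the successor state follows the transition matrix row.
    The returned GroundTruth carries an empty (0-channel) template array.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    n = config.n_samples
    fs = config.sampling_rate
    means = config.mean_durations_ms * fs / 1000.0  # samples
    p = 1.0 / np.maximum(means, 1.0)
    T = config.transition_matrix

    labels = np.empty(n, dtype=np.int64)
    segments: list[tuple[int, int, int, int]] = []
    if config.n_states == 1:
        state = 0
    else:
        state = int(rng.integers(config.n_states))
    pos = 0
    while pos < n:
        length = int(rng.geometric(p[state]))
        end = min(pos + length, n)
        prev_pol = segments[-1][3] if segments else 1
        polarity = -prev_pol if rng.random() < config.polarity_flip_prob else prev_pol
        labels[pos:end] = state
        segments.append((state, pos, end, polarity))
        pos = end
        if config.n_states > 1:
            state = int(rng.choice(config.n_states, p=T[state]))
    return GroundTruth(
        templates=np.empty((config.n_states, 0)),
        label_sequence=labels,
        segment_table=segments,
    )


def synthesize_recording(
    templates: np.ndarray,
    ground_truth: GroundTruth,
    config: GeneratorConfig,
    channel_names: Optional[list[str]] = None,
    positions: Optional[np.ndarray] = None,
) -> EEGRecording:
    """Render the EEG: sample t = polarity * envelope(t) * map[label(t)] + noise.

    The envelope is a rectified sinusoid |sin(2*pi*f*t)| scaled to mean 1,
    mimicking alpha-band GFP fluctuation so that GFP peaks exist.
    """
    templates = np.asarray(templates, dtype=float)
    if templates.shape[0] != config.n_states or templates.shape[1] != config.n_channels:
        raise ValueError("templates shape must be (n_states, n_channels)")
    if channel_names is None:
        channel_names = list(default_channels(config.n_channels))
    if positions is None:
        positions = channel_positions(channel_names)

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    n = len(ground_truth.label_sequence)
    t = np.arange(n) / config.sampling_rate
    envelope = np.abs(np.sin(2.0 * np.pi * config.envelope_freq * t)) * (np.pi / 2.0)

    polarity = np.ones(n)
    for state, start, end, pol in ground_truth.segment_table:
        polarity[start:end] = pol

    data = templates[ground_truth.label_sequence].T * (envelope * polarity)
    if config.noise_sigma > 0:
        data = data + rng.normal(scale=config.noise_sigma, size=data.shape)
    return EEGRecording(
        data=data,
        sampling_rate=config.sampling_rate,
        channel_names=list(channel_names),
        channel_positions=positions,
        provenance=[f"synthesize(seed={config.seed}, noise_sigma={config.noise_sigma})"],
    )


@dataclass
class ArtifactSpec:
    """One injected artifact: channel/time span in seconds."""

    channel: str
    start_s: float
    end_s: float
    amplitude: float = 1.0  # burst scale or flat value


def inject_artifacts(
    recording: EEGRecording,
    flat_channel_spec: Sequence[ArtifactSpec] = (),
    noisy_channel_spec: Sequence[ArtifactSpec] = (),
    burst_spec: Sequence[ArtifactSpec] = (),
    seed: int = 0,
) -> EEGRecording:
    """Plant flatlines, decorrelated-noise channels and amplitude bursts.

    Flat spans hold a constant value; noisy channels are replaced by
    independent Gaussian noise over their span; bursts add high-amplitude
    transients. Returns a new recording whose provenance logs every
    injection. Empty specs return the recording unchanged (bit-identical
    data).
    """
    if not (flat_channel_spec or noisy_channel_spec or burst_spec):
        return recording
    claimed: dict[str, list[tuple[float, float]]] = {}
    for spec in [*flat_channel_spec, *noisy_channel_spec]:
        for s0, s1 in claimed.get(spec.channel, []):
            if spec.start_s < s1 and s0 < spec.end_s:
                raise ValueError(f"overlapping artifact specs on channel {spec.channel}")
        claimed.setdefault(spec.channel, []).append((spec.start_s, spec.end_s))

    rng = np.random.default_rng(seed)
    data = recording.data.copy()
    fs = recording.sampling_rate
    log: list[str] = []
    name_to_idx = {c: i for i, c in enumerate(recording.channel_names)}

    def span(spec: ArtifactSpec) -> tuple[int, int, int]:
        if spec.channel not in name_to_idx:
            raise ValueError(f"unknown channel {spec.channel}")
        i0, i1 = int(round(spec.start_s * fs)), int(round(spec.end_s * fs))
        if not (0 <= i0 < i1 <= recording.n_samples):
            raise ValueError(f"artifact span out of range: {spec}")
        return name_to_idx[spec.channel], i0, i1

    for spec in flat_channel_spec:
        ch, i0, i1 = span(spec)
        data[ch, i0:i1] = spec.amplitude
        log.append(f"flat(ch={spec.channel}, {spec.start_s}-{spec.end_s}s)")
    for spec in noisy_channel_spec:
        ch, i0, i1 = span(spec)
        scale = spec.amplitude * max(np.std(recording.data), 1e-12)
        data[ch, i0:i1] = rng.normal(scale=scale, size=i1 - i0)
        log.append(f"noise(ch={spec.channel}, {spec.start_s}-{spec.end_s}s)")
    for spec in burst_spec:
        ch, i0, i1 = span(spec)
        data[ch, i0:i1] += spec.amplitude * np.sin(
            2.0 * np.pi * 8.0 * np.arange(i1 - i0) / fs
        )
        log.append(f"burst(ch={spec.channel}, {spec.start_s}-{spec.end_s}s, amp={spec.amplitude})")
    return recording.copy_with(data, "inject_artifacts[" + "; ".join(log) + "]")


def simulate_subject(
    config: GeneratorConfig,
    templates: Optional[np.ndarray] = None,
    min_separation: float = 0.3,
) -> tuple[EEGRecording, GroundTruth]:
    """Convenience: templates (unless given) + state sequence + rendering."""
    if templates is None:
        templates = make_template_maps(
            config.n_channels, config.n_states, seed=config.seed, min_separation=min_separation
        )
    gt = sample_state_sequence(config)
    gt = GroundTruth(
        templates=templates,
        label_sequence=gt.label_sequence,
        segment_table=gt.segment_table,
    )
    rec = synthesize_recording(templates, gt, config)
    return rec, gt
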