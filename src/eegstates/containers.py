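"""In-memory containers shared across the pipeline.

All potential values are in microvolts; time axes are in samples at the
recording's sampling rate. Scalp maps are stored average-referenced (each
map sums to ~0 across channels).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = [
    "EEGRecording",
    "EpochedData",
    "TemplateSet",
    "GfpSeries",
    "MicrostateSegmentation",
    "MicrostateParameters",
    "TransitionTable",
    "TestResult",
]


@dataclass
class EEGRecording:
    """Continuous multichannel EEG.

    Attributes
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Potentials in microvolts.
    sampling_rate : float
        Hz.
    channel_names : list of str
    channel_positions : ndarray, shape (n_channels, 3)
        Unit-sphere electrode coordinates.
    provenance : list of str
        Ordered record of processing steps applied.
    boundaries : list of int
        Sample indices (in the *current* data) where a discontinuity was
        introduced by excising data; epochs must not span them.
    """

    data: np.ndarray
    sampling_rate: float
    channel_names: list[str]
    channel_positions: np.ndarray
    provenance: list[str] = field(default_factory=list)
    boundaries: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError("channel_names length does not match data")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data must be finite")
        self.channel_positions = np.asarray(self.channel_positions, dtype=float)
        norms = np.linalg.norm(self.channel_positions, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("channel positions must be unit-norm")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    def copy_with(self, data: np.ndarray, step: str, **kw) -> "EEGRecording":
        """New recording with replaced data and one more provenance entry."""
        new = replace(
            self,
            data=data,
            provenance=[*self.provenance, step],
            **kw,
        )
        return new


@dataclass
class EpochedData:
    """Fixed-length, non-overlapping clean epochs."""

    epochs: np.ndarray  # (n_epochs, n_channels, n_samples_per_epoch)
    epoch_length: float  # seconds
    sampling_rate: float
    channel_names: list[str]
    rejected_windows: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be 3-D (epochs x channels x samples)")
        n = self.epoch_length * self.sampling_rate
        if abs(n - round(n)) > 1e-9:
            raise ValueError("epoch_length x sampling_rate must be integral")

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]


@dataclass
class TemplateSet:
    """K cluster-centre topographies with labels and fit diagnostics.

    ``maps`` has shape (K, n_channels); each row is unit L2 norm and
    average-referenced. ``labels`` are the canonical class names (e.g.
    'A'..'D') or None when not yet assigned.
    """

    maps: np.ndarray
    channel_names: list[str]
    labels: Optional[list[str]] = None
    gev_total: Optional[float] = None
    gev_per_class: Optional[np.ndarray] = None
    source: str = ""

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=float)
        if self.maps.ndim != 2:
            raise ValueError("maps must be 2-D (K x channels)")

    @property
    def n_classes(self) -> int:
        return self.maps.shape[0]

    def ordered_by_label(self) -> "TemplateSet":
        """Reorder maps alphabetically by class label (A, B, C, D)."""
        if self.labels is None:
            return self
        order = np.argsort(self.labels)
        return TemplateSet(
            maps=self.maps[order],
            channel_names=self.channel_names,
            labels=[self.labels[i] for i in order],
            gev_total=self.gev_total,
            gev_per_class=None if self.gev_per_class is None else self.gev_per_class[order],
            source=self.source,
        )


@dataclass
class GfpSeries:
    """Global field power per sample, organised per epoch."""

    values: list[np.ndarray]  # one 1-D array per epoch
    sampling_rate: float
    peak_indices: Optional[list[np.ndarray]] = None  # per-epoch peak samples


@dataclass
class MicrostateSegmentation:
    """Per-sample class labels for one subject's epoched data."""

    labels: list[np.ndarray]  # per-epoch int arrays
    assignment_corr: list[np.ndarray]  # per-sample |spatial correlation|
    gfp: list[np.ndarray]
    sampling_rate: float
    n_classes: int

    def __post_init__(self) -> None:
        for lab, cor, g in zip(self.labels, self.assignment_corr, self.gfp):
            if not (len(lab) == len(cor) == len(g)):
                raise ValueError("per-epoch field lengths inconsistent")


@dataclass
class MicrostateParameters:
    """Per-class temporal parameters for one subject.

    ``duration_ms[k]`` is NaN when class k has no interior (non-boundary)
    run — the value is missing, not zero.
    """

    duration_ms: np.ndarray
    occurrence_per_s: np.ndarray
    coverage_pct: np.ndarray
    gev_per_class: Optional[np.ndarray] = None
    gev_total: Optional[float] = None


@dataclass
class TransitionTable:
    """Observed and expected transition percentages over ordered class pairs.

    Both matrices are K x K with zero diagonal; their off-diagonal entries
    each sum to 100.
    """

    observed_pct: np.ndarray
    expected_pct: np.ndarray
    segment_counts: np.ndarray

    @property
    def n_classes(self) -> int:
        return self.observed_pct.shape[0]


@dataclass
class TestResult:
    """One statistical test outcome."""

    statistic: float
    p_value: float
    test_name: str
    p_adjusted: Optional[float] = None
    effect_size: Optional[float] = None
    n_per_group: Optional[tuple[int, int]] = None
    extra: dict = field(default_factory=dict)
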