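"""Backfitting: label every sample with its best template, then extract
duration / occurrence / coverage / transition parameters.

Labelling is polarity-invariant and GEV-optimal per sample: each scalp map
gets the template of maximal absolute spatial correlation. Samples whose
GFP is numerically zero (the amplitude envelope crosses zero) inherit the
previous sample's label so they never create spurious segments.
"""

from __future__ import annotations

import numpy as np

from .containers import (
    EpochedData,
    MicrostateParameters,
    MicrostateSegmentation,
    TemplateSet,
    TransitionTable,
)

__all__ = [
    "backfit",
    "smooth_labels",
    "runs",
    "compute_parameters",
    "transition_matrix",
    "expected_transitions",
    "segment_and_parameterize",
]


def backfit(epochs: EpochedData, templates: TemplateSet) -> MicrostateSegmentation:
    """Assign each sample the class of maximal |spatial correlation|.

    Ties resolve to the lowest class index. Near-zero-GFP samples
    (GFP < 1e-12) carry the previous label forward; dead samples at the
    start of an epoch inherit the first live label, so amplitude-envelope
    zeros never fabricate segments.
    """
    T = np.asarray(templates.maps, dtype=float)
    if T.shape[1] != epochs.epochs.shape[1]:
        raise ValueError("template and epoch channel counts differ")
    T = T - T.mean(axis=1, keepdims=True)
    T = T / np.linalg.norm(T, axis=1, keepdims=True)
    all_labels, all_corr, all_gfp = [], [], []
    C = T.shape[1]
    for ep in epochs.epochs:
        V = ep - ep.mean(axis=0, keepdims=True)  # (C, n)
        norms = np.linalg.norm(V, axis=0)
        g = norms / np.sqrt(C)
        corr = np.zeros((T.shape[0], V.shape[1]))
        nz = norms > 0
        corr[:, nz] = (T @ V[:, nz]) / norms[nz]
        labels = np.argmax(np.abs(corr), axis=0)
        best = np.abs(corr)[labels, np.arange(V.shape[1])]
        # carry-forward through zero-GFP samples; leading dead samples
        # take the first live label
        dead = g < 1e-12
        if dead.any() and not dead.all():
            live = np.nonzero(~dead)[0]
            lab = labels.copy()
            first = live[0]
            lab[:first] = lab[first]
            prev = lab[first]
            for t in range(first, len(lab)):
                if dead[t]:
                    lab[t] = prev
                else:
                    prev = lab[t]
            labels = lab
        all_labels.append(labels.astype(np.int64))
        all_corr.append(best)
        all_gfp.append(g)
    return MicrostateSegmentation(
        labels=all_labels,
        assignment_corr=all_corr,
        gfp=all_gfp,
        sampling_rate=epochs.sampling_rate,
        n_classes=T.shape[0],
    )


def runs(labels: np.ndarray) -> list[tuple[int, int, int]]:
    """Maximal constant-label runs as (label, start, end) with end exclusive."""
    if len(labels) == 0:
        return []
    change = np.nonzero(np.diff(labels))[0] + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [len(labels)]))
    return [(int(labels[s]), int(s), int(e)) for s, e in zip(starts, ends)]


def smooth_labels(
    segmentation: MicrostateSegmentation,
    epochs: EpochedData,
    templates: TemplateSet,
    min_segment_ms: float = 0.0,
    max_iter: int = 100,
) -> MicrostateSegmentation:
    """Absorb segments shorter than ``min_segment_ms`` into a neighbour.

    Each sample of an offending segment is re-assigned to whichever
    neighbouring segment's template correlates better with it (absolute
    correlation); iterates until no short interior segment remains. The
    default threshold of 0 disables smoothing (identity).
    """
    if min_segment_ms < 0:
        raise ValueError("min_segment_ms must be >= 0")
    if min_segment_ms == 0:
        return segmentation
    fs = segmentation.sampling_rate
    min_len = int(np.ceil(min_segment_ms * fs / 1000.0))
    if min_len > epochs.epochs.shape[2]:
        raise ValueError("smoothing threshold longer than an epoch")
    T = np.asarray(templates.maps, dtype=float)
    T = T - T.mean(axis=1, keepdims=True)
    T = T / np.linalg.norm(T, axis=1, keepdims=True)

    new_labels = []
    for ep, labels in zip(epochs.epochs, segmentation.labels):
        V = ep - ep.mean(axis=0, keepdims=True)
        norms = np.maximum(np.linalg.norm(V, axis=0), 1e-30)
        corr = np.abs(T @ V) / norms  # (K, n)
        lab = labels.copy()
        for _ in range(max_iter):
            rs = runs(lab)
            short = [
                (i, r)
                for i, r in enumerate(rs)
                if (r[2] - r[1]) < min_len and len(rs) > 1
            ]
            if not short:
                break
            changed = False
            # absorb the shortest run first for determinism
            short.sort(key=lambda ir: (ir[1][2] - ir[1][1], ir[1][1]))
            i, (state, s, e) = short[0]
            left = rs[i - 1][0] if i > 0 else None
            right = rs[i + 1][0] if i < len(rs) - 1 else None
            for t in range(s, e):
                if left is None:
                    lab[t] = right
                elif right is None:
                    lab[t] = left
                else:
                    lab[t] = left if corr[left, t] >= corr[right, t] else right
            changed = True
            if not changed:
                break
        new_labels.append(lab)
    return MicrostateSegmentation(
        labels=new_labels,
        assignment_corr=segmentation.assignment_corr,
        gfp=segmentation.gfp,
        sampling_rate=fs,
        n_classes=segmentation.n_classes,
    )


def compute_parameters(segmentation: MicrostateSegmentation) -> MicrostateParameters:
    """Per-class mean duration (ms), occurrence (1/s) and coverage (%).

    Duration averages only *interior* runs (those not touching an epoch
    boundary): truncated runs would bias the estimate downwards. Occurrence
    counts every run, truncated or not, per second of retained data.
    Coverage is the per-class share of samples. A class with no interior run
    has missing (NaN) duration, not zero.
    """
    K = segmentation.n_classes
    fs = segmentation.sampling_rate
    total_samples = sum(len(l) for l in segmentation.labels)
    if total_samples == 0:
        raise ValueError("empty segmentation")
    interior_lengths: list[list[int]] = [[] for _ in range(K)]
    run_counts = np.zeros(K)
    sample_counts = np.zeros(K)
    for labels in segmentation.labels:
        n = len(labels)
        for state, s, e in runs(labels):
            run_counts[state] += 1
            sample_counts[state] += e - s
            if s > 0 and e < n:
                interior_lengths[state].append(e - s)
    duration_ms = np.array(
        [
            np.mean(lens) * 1000.0 / fs if lens else np.nan
            for lens in interior_lengths
        ]
    )
    total_seconds = total_samples / fs
    occurrence = run_counts / total_seconds
    coverage = 100.0 * sample_counts / total_samples
    return MicrostateParameters(
        duration_ms=duration_ms,
        occurrence_per_s=occurrence,
        coverage_pct=coverage,
    )


def transition_matrix(segmentation: MicrostateSegmentation) -> TransitionTable:
    """Observed transition percentages over ordered class pairs.

    Counts consecutive-segment pairs (i -> j, i != j) within epochs only —
    never across epoch boundaries — and normalises to percentages.
    """
    K = segmentation.n_classes
    counts = np.zeros((K, K))
    seg_counts = np.zeros(K)
    for labels in segmentation.labels:
        rs = runs(labels)
        for state, _, _ in rs:
            seg_counts[state] += 1
        for (a, _, _), (b, _, _) in zip(rs[:-1], rs[1:]):
            counts[a, b] += 1
    total = counts.sum()
    if total == 0:
        raise ValueError("no transitions in segmentation")
    observed = 100.0 * counts / total
    expected = expected_transitions(seg_counts)
    return TransitionTable(
        observed_pct=observed, expected_pct=expected, segment_counts=seg_counts
    )


def expected_transitions(segment_counts: np.ndarray) -> np.ndarray:
    """Null transition percentages under label-independent segment order.

    With q_k the segment-count fraction of class k, the null expectation is
    expected(i->j) = 100 * q_i q_j / sum_{a != b} q_a q_b (diagonal zero).
    """
    q = np.asarray(segment_counts, dtype=float)
    if (q > 0).sum() < 2:
        raise ValueError("expected transitions need at least 2 occupied classes")
    q = q / q.sum()
    outer = np.outer(q, q)
    np.fill_diagonal(outer, 0.0)
    return 100.0 * outer / outer.sum()


def segment_and_parameterize(
    epochs: EpochedData,
    templates: TemplateSet,
    min_segment_ms: float = 0.0,
) -> tuple[MicrostateSegmentation, MicrostateParameters, TransitionTable]:
    """Backfit (+ optional smoothing) and extract all parameter families,
    including the per-class GEV of the final labelling."""
    from .maps import gev as _gev

    seg = backfit(epochs, templates)
    if min_segment_ms > 0:
        seg = smooth_labels(seg, epochs, templates, min_segment_ms=min_segment_ms)
    params = compute_parameters(seg)
    # GEV of the final labelling over all samples
    V = np.concatenate(
        [ep - ep.mean(axis=0, keepdims=True) for ep in epochs.epochs], axis=1
    ).T
    labels = np.concatenate(seg.labels)
    gvals = np.concatenate(seg.gfp)
    total, per_class = _gev(V, labels, templates.maps, gvals)
    params.gev_total = total
    params.gev_per_class = per_class
    table = transition_matrix(seg)
    return seg, params, table
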