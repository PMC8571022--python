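"""Microstate template derivation.

GFP-peak extraction, atomize-and-agglomerate hierarchical clustering
(AAHC), global explained variance (GEV), permutation alignment of subject
template sets, group-mean templates and canonical A-D labelling.

All topographic comparisons are polarity-invariant: a map and its negation
describe the same microstate, so correlations enter as absolute values and
cluster centres are principal directions, never plain means (which would
cancel under sign flips).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .containers import EpochedData, GfpSeries, TemplateSet
from .montage import channel_positions

__all__ = [
    "gfp",
    "find_gfp_peaks",
    "spatial_correlation",
    "peak_maps",
    "aahc_cluster",
    "gev",
    "align_subject_maps",
    "group_mean_templates",
    "canonical_archetypes",
    "label_canonical",
    "subject_templates",
]


def gfp(epochs: EpochedData) -> GfpSeries:
    """Global field power: the spatial SD of the scalp map at each sample.

    GFP(t) = sqrt( mean_c (v_c(t) - mean_c' v_c'(t))^2 ).
    """
    if epochs.epochs.shape[1] < 2:
        raise ValueError("GFP requires at least 2 channels")
    vals = []
    for ep in epochs.epochs:
        centered = ep - ep.mean(axis=0, keepdims=True)
        vals.append(np.sqrt((centered**2).mean(axis=0)))
    return GfpSeries(values=vals, sampling_rate=epochs.sampling_rate)


def _peaks_1d(x: np.ndarray, min_distance: int) -> np.ndarray:
    """Strict local maxima, greedily thinned to the given minimum distance.

    Candidates are ranked by height (ties: earlier sample wins); boundary
    samples are never peaks.
    """
    n = len(x)
    if n < 3:
        return np.array([], dtype=int)
    interior = np.arange(1, n - 1)
    cand = interior[(x[1:-1] > x[:-2]) & (x[1:-1] > x[2:])]
    if cand.size == 0:
        return cand
    order = np.lexsort((cand, -x[cand]))  # height desc, then earlier index
    kept: list[int] = []
    taken = np.zeros(n, dtype=bool)
    for i in cand[order]:
        if not taken[i]:
            kept.append(int(i))
            lo = max(0, i - min_distance + 1)
            taken[lo : i + min_distance] = True
    return np.array(sorted(kept), dtype=int)


def find_gfp_peaks(gfp_series: GfpSeries, min_distance_ms: float = 10.0) -> GfpSeries:
    """Locate GFP peaks per epoch; peaks closer than ``min_distance_ms`` are
    thinned keeping the higher (earlier on ties)."""
    dist = max(1, int(round(min_distance_ms * gfp_series.sampling_rate / 1000.0)))
    peaks = [_peaks_1d(v, dist) for v in gfp_series.values]
    return GfpSeries(
        values=gfp_series.values, sampling_rate=gfp_series.sampling_rate, peak_indices=peaks
    )


def spatial_correlation(u: np.ndarray, v: np.ndarray, ignore_polarity: bool = True) -> float:
    """Pearson correlation of two scalp maps across channels.

    With ``ignore_polarity`` (the default throughout microstate analysis)
    the absolute value is returned, mapping to [0, 1].
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("maps must share the channel set")
    uc = u - u.mean()
    vc = v - v.mean()
    nu, nv = np.linalg.norm(uc), np.linalg.norm(vc)
    if nu == 0 or nv == 0:
        raise ValueError("zero-variance map")
    r = float(uc @ vc / (nu * nv))
    return abs(r) if ignore_polarity else r


def peak_maps(epochs: EpochedData, gfp_series: GfpSeries) -> tuple[np.ndarray, np.ndarray]:
    """Collect the average-referenced maps at GFP peaks.

    Returns ``(maps, gfp_values)`` with maps of shape (n_peaks, n_channels).
    """
    if gfp_series.peak_indices is None:
        raise ValueError("run find_gfp_peaks first")
    maps, gvals = [], []
    for ep, g, pk in zip(epochs.epochs, gfp_series.values, gfp_series.peak_indices):
        centered = ep - ep.mean(axis=0, keepdims=True)
        maps.append(centered[:, pk].T)
        gvals.append(g[pk])
    return np.concatenate(maps, axis=0), np.concatenate(gvals)


# ---------------------------------------------------------------------------
# AAHC
# ---------------------------------------------------------------------------


def _top_eig(S: np.ndarray) -> tuple[np.ndarray, float]:
    """Leading eigenpair of a symmetric PSD scatter matrix."""
    w, V = np.linalg.eigh(S)
    return V[:, -1], float(w[-1])


def aahc_cluster(
    maps: np.ndarray, gfp_values: np.ndarray | None = None, k: int = 4
) -> tuple[TemplateSet, np.ndarray]:
    """Atomize-and-agglomerate hierarchical clustering of GFP-peak maps.

    Every map starts as a singleton cluster. Each iteration *atomizes* the
    cluster explaining the least variance: it is deleted and each orphaned
    map is re-assigned to the surviving cluster whose template it matches
    best in absolute spatial correlation. Clustering operates on
    GFP-normalised (unit-norm) maps, which makes the result invariant to
    per-map scaling and sign; the cluster template is the first principal
    direction of its member maps (polarity-proof), so for a cluster with
    scatter matrix S = sum_t u_t u_t^T the template is the top eigenvector
    and the cluster's summed squared correlation is exactly the top
    eigenvalue. Iteration stops at ``k`` clusters.

    Parameters
    ----------
    maps : (n_maps, n_channels) average-referenced maps (GFP-peak maps).
    gfp_values : optional per-map GFP; used to report the GFP-weighted GEV
        of the final partition (clustering itself is amplitude-blind).
    k : target number of clusters.

    Returns
    -------
    (TemplateSet, assignment) where assignment[i] is the final cluster index
    of map i.
    """
    V = np.asarray(maps, dtype=float)
    if V.ndim != 2:
        raise ValueError("maps must be 2-D (n_maps x n_channels)")
    n, C = V.shape
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}]")
    V = V - V.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(V, axis=1)
    if np.any(norms < 1e-14):
        raise ValueError("zero-variance map in input")
    U = V / norms[:, None]  # GFP-normalised maps

    members: list[list[int] | None] = [[i] for i in range(n)]
    templates = U.copy()  # (n, C); row for dead clusters is stale
    lam = np.ones(n)  # top eigenvalue of each singleton's scatter
    scatters: dict[int, np.ndarray] = {}
    alive = np.ones(n, dtype=bool)
    n_alive = n

    def recompute(ci: int) -> None:
        S = scatters.get(ci)
        if S is None:
            S = U[members[ci]].T @ U[members[ci]]
            scatters[ci] = S
        t, l = _top_eig(S)
        templates[ci] = t
        lam[ci] = l

    while n_alive > k:
        alive_idx = np.nonzero(alive)[0]
        worst = alive_idx[int(np.argmin(lam[alive_idx]))]
        orphans = members[worst]
        alive[worst] = False
        members[worst] = None
        scatters.pop(worst, None)
        n_alive -= 1
        alive_idx = np.nonzero(alive)[0]

        scores = np.abs(U[orphans] @ templates[alive_idx].T)  # (n_orphans, n_alive)
        dest = alive_idx[np.argmax(scores, axis=1)]
        changed = set()
        for t_idx, ci in zip(orphans, dest):
            ci = int(ci)
            if ci in scatters:
                scatters[ci] += np.outer(U[t_idx], U[t_idx])
            elif len(members[ci]) >= 1:
                scatters[ci] = U[members[ci]].T @ U[members[ci]] + np.outer(U[t_idx], U[t_idx])
            members[ci].append(int(t_idx))
            changed.add(ci)
        for ci in changed:
            recompute(ci)

    alive_idx = np.nonzero(alive)[0]
    assignment = np.empty(n, dtype=int)
    final_templates = np.empty((len(alive_idx), C))
    for new_i, ci in enumerate(alive_idx):
        for t_idx in members[ci]:
            assignment[t_idx] = new_i
        final_templates[new_i] = templates[ci]
    g = norms / np.sqrt(C) if gfp_values is None else np.asarray(gfp_values, float)
    gev_total, gev_per = gev(V, assignment, final_templates, g)
    ts = TemplateSet(
        maps=final_templates,
        channel_names=[],
        gev_total=gev_total,
        gev_per_class=gev_per,
    )
    return ts, assignment


def gev(
    maps: np.ndarray,
    labels: np.ndarray,
    templates: np.ndarray,
    gfp_values: np.ndarray,
) -> tuple[float, np.ndarray]:
    """Global explained variance of a labelling.

    GEV = sum_t (GFP_t * corr(v_t, T_label(t)))^2 / sum_t GFP_t^2, together
    with its per-class decomposition (which sums to the total).
    """
    V = np.asarray(maps, dtype=float)
    V = V - V.mean(axis=1, keepdims=True)
    T = np.asarray(templates, dtype=float)
    T = T - T.mean(axis=1, keepdims=True)
    T = T / np.linalg.norm(T, axis=1, keepdims=True)
    g = np.asarray(gfp_values, dtype=float)
    denom = float((g**2).sum())
    if denom == 0:
        raise ValueError("all-zero GFP")
    norms = np.linalg.norm(V, axis=1)
    corr = np.zeros(len(V))
    nz = norms > 0
    corr[nz] = np.einsum("ij,ij->i", V[nz] / norms[nz, None], T[labels[nz]])
    contrib = (g * np.abs(corr)) ** 2
    K = T.shape[0]
    per_class = np.array([contrib[labels == k_].sum() for k_ in range(K)]) / denom
    return float(per_class.sum()), per_class


# ---------------------------------------------------------------------------
# Alignment across subjects and canonical labelling
# ---------------------------------------------------------------------------


def _best_perm_signs(
    maps: np.ndarray, ref: np.ndarray
) -> tuple[tuple[int, ...], np.ndarray, float]:
    """Exhaustive permutation + per-map sign maximizing sum of squared
    correlations with the reference maps."""
    K = maps.shape[0]
    R = np.empty((K, K))
    for i in range(K):
        for j in range(K):
            R[i, j] = spatial_correlation(maps[i], ref[j], ignore_polarity=False)
    best, best_score = None, -np.inf
    for perm in itertools.permutations(range(K)):
        score = sum(R[perm[j], j] ** 2 for j in range(K))
        if score > best_score:
            best_score, best = score, perm
    signs = np.array([1.0 if R[best[j], j] >= 0 else -1.0 for j in range(K)])
    return best, signs, float(best_score)


def align_subject_maps(
    template_sets: list[TemplateSet],
    max_iter: int = 100,
    tol: float = 1e-6,
) -> tuple[list[TemplateSet], list[float]]:
    """Align each subject's K maps (order and sign) to an evolving group mean.

    Iterates: (a) for every subject choose, exhaustively over the K!
    permutations and per-map signs, the arrangement maximizing the summed
    squared correlation with the current mean; (b) recompute the mean from
    the aligned maps and renormalise. Stops when the mean changes by less
    than ``tol`` (max absolute entry) or after ``max_iter`` iterations.

    Returns the aligned sets and the per-iteration objective values (the
    objective is non-decreasing).
    """
    if not template_sets:
        raise ValueError("empty group")
    K = template_sets[0].n_classes
    chans = template_sets[0].channel_names
    for ts in template_sets:
        if ts.n_classes != K or ts.channel_names != chans:
            raise ValueError("inconsistent template sets")
    stack = [ts.maps.copy() for ts in template_sets]
    if len(stack) == 1:
        return [template_sets[0]], [float(K)]

    mean = stack[0] / np.linalg.norm(stack[0], axis=1, keepdims=True)
    objective: list[float] = []
    aligned = stack
    for _ in range(max_iter):
        total = 0.0
        new_aligned = []
        for maps in stack:
            perm, signs, score = _best_perm_signs(maps, mean)
            new_aligned.append(maps[list(perm)] * signs[:, None])
            total += score
        objective.append(total)
        new_mean = np.mean(new_aligned, axis=0)
        new_mean /= np.linalg.norm(new_mean, axis=1, keepdims=True)
        aligned = new_aligned
        if np.max(np.abs(new_mean - mean)) < tol:
            mean = new_mean
            break
        mean = new_mean
    out = [
        TemplateSet(maps=m, channel_names=chans, source=ts.source)
        for m, ts in zip(aligned, template_sets)
    ]
    return out, objective


def group_mean_templates(aligned_sets: list[TemplateSet], source: str = "group") -> TemplateSet:
    """Polarity-reconciled per-class average of aligned subject maps,
    renormalised to unit norm."""
    if not aligned_sets:
        raise ValueError("empty group")
    K = aligned_sets[0].n_classes
    chans = aligned_sets[0].channel_names
    ref = aligned_sets[0].maps
    acc = np.zeros_like(ref)
    for ts in aligned_sets:
        for j in range(K):
            r = spatial_correlation(ts.maps[j], ref[j], ignore_polarity=False)
            acc[j] += np.sign(r) * ts.maps[j] if r != 0 else ts.maps[j]
    acc /= len(aligned_sets)
    acc /= np.linalg.norm(acc, axis=1, keepdims=True)
    return TemplateSet(maps=acc, channel_names=chans, source=source)


def canonical_archetypes(channel_names: list[str]) -> TemplateSet:
    """Built-in idealized A-D archetype maps on the given montage channels.

    Smooth fields in head coordinates (x: right, y: anterior, z: up):
    A - left-posterior / right-anterior diagonal gradient;
    B - the mirrored diagonal;
    C - anterior-posterior gradient with an occipital emphasis;
    D - fronto-central focal extreme (von Mises-Fisher bump near FCz).
    """
    P = channel_positions(channel_names)
    x, y, z = P[:, 0], P[:, 1], P[:, 2]
    fcz = np.array([0.0, 0.4, 0.9])
    fcz /= np.linalg.norm(fcz)
    fields = [
        x + y,  # A
        y - x,  # B
        -y + 0.5 * z,  # C
        np.exp(2.5 * (P @ fcz - 1.0)),  # D
    ]
    M = np.array([f - f.mean() for f in fields])
    M /= np.linalg.norm(M, axis=1, keepdims=True)
    return TemplateSet(maps=M, channel_names=list(channel_names), labels=["A", "B", "C", "D"])


def label_canonical(
    templates: TemplateSet, archetypes: TemplateSet | None = None
) -> TemplateSet:
    """Assign class names A-D by exhaustive one-to-one matching.

    Over all 24 permutations, chooses the assignment maximizing the total
    absolute spatial correlation with the archetype maps.
    """
    if templates.n_classes != 4:
        raise ValueError("canonical labelling expects K = 4")
    if archetypes is None:
        archetypes = canonical_archetypes(templates.channel_names)
    R = np.empty((4, 4))
    for i in range(4):
        for j in range(4):
            R[i, j] = spatial_correlation(templates.maps[i], archetypes.maps[j])
    best, best_score = None, -np.inf
    for perm in itertools.permutations(range(4)):
        score = sum(R[i, perm[i]] for i in range(4))
        if score > best_score:
            best_score, best = score, perm
    labels = [archetypes.labels[best[i]] for i in range(4)]
    return TemplateSet(
        maps=templates.maps,
        channel_names=templates.channel_names,
        labels=labels,
        gev_total=templates.gev_total,
        gev_per_class=templates.gev_per_class,
        source=templates.source,
    )


def subject_templates(
    epochs: EpochedData,
    k: int = 4,
    min_distance_ms: float = 10.0,
    source: str = "",
) -> TemplateSet:
    """Per-subject pipeline: GFP -> peaks -> AAHC -> K templates."""
    g = gfp(epochs)
    g = find_gfp_peaks(g, min_distance_ms=min_distance_ms)
    V, gv = peak_maps(epochs, g)
    ts, _ = aahc_cluster(V, gv, k=k)
    return TemplateSet(
        maps=ts.maps,
        channel_names=list(epochs.channel_names),
        gev_total=ts.gev_total,
        gev_per_class=ts.gev_per_class,
        source=source,
    )
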