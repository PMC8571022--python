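"""Deliberately naive reference implementations used as test oracles.

These recompute everything from scratch at every step with explicit loops,
trading speed for obvious correctness; they must stay independent of the
package's optimised code paths.
"""

import numpy as np


def naive_aahc(maps: np.ndarray, k: int) -> np.ndarray:
    """Step-by-step AAHC: returns the cluster assignment of each map.

    Definitions mirrored from first principles: maps are centred and
    normalised (amplitude-blind clustering); a cluster's template is the
    leading eigenvector of the summed outer products of its member maps;
    its quality is the summed squared projection of members onto the
    template; the worst cluster is dissolved and each orphan joins the
    surviving cluster of highest absolute cosine to its template (scored
    against the pre-dissolution templates).
    """
    V = np.asarray(maps, dtype=float)
    V = V - V.mean(axis=1, keepdims=True)
    V = V / np.linalg.norm(V, axis=1, keepdims=True)
    n = len(V)
    clusters: list[list[int]] = [[i] for i in range(n)]

    def template(members):
        if len(members) == 1:
            return V[members[0]]
        S = np.zeros((V.shape[1], V.shape[1]))
        for t in members:
            S += np.outer(V[t], V[t])
        w, vec = np.linalg.eigh(S)
        return vec[:, -1]

    def quality(members):
        if len(members) == 1:
            return 1.0  # unit map projected onto itself, exactly
        T = template(members)
        return sum(float(V[t] @ T) ** 2 for t in members)

    while len(clusters) > k:
        quals = [quality(m) for m in clusters]
        worst = int(np.argmin(quals))
        orphans = clusters.pop(worst)
        temps = [template(m) for m in clusters]
        dests = []
        for t in orphans:
            u = V[t] / np.linalg.norm(V[t])
            scores = [abs(float(u @ T)) for T in temps]
            dests.append(int(np.argmax(scores)))
        for t, d in zip(orphans, dests):
            clusters[d].append(t)

    assignment = np.empty(n, dtype=int)
    for ci, members in enumerate(clusters):
        for t in members:
            assignment[t] = ci
    return assignment


def naive_gev(maps, labels, templates, gfp_values):
    """GEV from the definition, one sample at a time."""
    total = 0.0
    denom = 0.0
    for v, lab, g in zip(maps, labels, gfp_values):
        v = np.asarray(v, float)
        v = v - v.mean()
        T = np.asarray(templates[lab], float)
        T = T - T.mean()
        r = float(v @ T / (np.linalg.norm(v) * np.linalg.norm(T)))
        total += (g * abs(r)) ** 2
        denom += g**2
    return total / denom


def partitions_equal(a: np.ndarray, b: np.ndarray) -> bool:
    """True when two assignments induce the same partition (up to relabel)."""
    mapping = {}
    for x, y in zip(a, b):
        if x in mapping:
            if mapping[x] != y:
                return False
        else:
            mapping[x] = y
    return len(set(mapping.values())) == len(mapping)
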