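"""Electrode montage utilities.

Channel coordinates come from the idealized easycap ``M1`` layout (the cap
geometry of actiCAP-style 64-channel systems placed by the extended 10/20
scheme). That layout lives on an exact sphere of radius 95 mm centred at the
origin, so projecting to the unit sphere is a pure rescaling.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

#: The 64 channel names of a standard actiCAP 64-channel cap (10/20-extended).
ACTICAP_64: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6", "T7", "C3", "Cz", "C4", "T8",
    "TP9", "CP5", "CP1", "CP2", "CP6", "TP10",
    "P7", "P3", "Pz", "P4", "P8", "PO9", "O1", "Oz", "O2", "PO10",
    "AF7", "AF3", "AF4", "AF8", "F5", "F1", "F2", "F6",
    "FT9", "FT7", "FC3", "FC4", "FT8", "FT10",
    "C5", "C1", "C2", "C6", "TP7", "CP3", "CPz", "CP4", "TP8",
    "P5", "P1", "P2", "P6", "PO7", "PO3", "POz", "PO4", "PO8",
)


@lru_cache(maxsize=8)
def _easycap_positions() -> dict[str, np.ndarray]:
    import mne

    montage = mne.channels.make_standard_montage("easycap-M1")
    return {k: np.asarray(v, dtype=float) for k, v in montage.get_positions()["ch_pos"].items()}


def channel_positions(channel_names: tuple[str, ...] | list[str] | None = None) -> np.ndarray:
    """Unit-sphere 3D positions for the given channels.

    Parameters
    ----------
    channel_names
        Channel names from the 10/20-extended nomenclature. Defaults to the
        64-channel actiCAP set.

    Returns
    -------
    ndarray of shape (n_channels, 3), each row unit-norm.
    """
    if channel_names is None:
        channel_names = ACTICAP_64
    pos = _easycap_positions()
    missing = [c for c in channel_names if c not in pos]
    if missing:
        raise KeyError(f"channels not in the easycap-M1 montage: {missing}")
    arr = np.array([pos[c] for c in channel_names], dtype=float)
    return arr / np.linalg.norm(arr, axis=1, keepdims=True)


def default_channels(n_channels: int) -> tuple[str, ...]:
    """First ``n_channels`` names of the actiCAP 64 layout (montage subset)."""
    if not 1 <= n_channels <= len(ACTICAP_64):
        raise ValueError(f"n_channels must be in [1, {len(ACTICAP_64)}], got {n_channels}")
    return ACTICAP_64[:n_channels]


def neighbor_table(positions: np.ndarray, k: int = 6) -> tuple[np.ndarray, np.ndarray]:
    """``k`` nearest neighbours of every electrode by great-circle distance.

    Returns ``(indices, weights)``: for each channel, the neighbour channel
    indices and inverse-distance weights normalised to sum to 1.
    """
    P = positions / np.linalg.norm(positions, axis=1, keepdims=True)
    cosang = np.clip(P @ P.T, -1.0, 1.0)
    dist = np.arccos(cosang)
    np.fill_diagonal(dist, np.inf)
    idx = np.argsort(dist, axis=1)[:, :k]
    d = np.take_along_axis(dist, idx, axis=1)
    w = 1.0 / np.maximum(d, 1e-9)
    w /= w.sum(axis=1, keepdims=True)
    return idx, w
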