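"""Preprocessing chain: raw continuous EEG to clean 2-s epochs.

Fixed stage order: resample -> band-pass + notch -> bad-channel detection ->
spherical-spline interpolation -> average reference -> 0.5-s window artifact
rejection -> 2-s epoching. Defaults are the thresholds of the target
acquisition protocol (250 Hz, 1-40 Hz, 50 Hz notch, 5 s flatline, 4 SD
noise, 0.8 neighbour correlation, 0.5-s/20-SD windows, 2-s epochs).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import scipy.signal
from scipy.special import eval_legendre

from .containers import EEGRecording, EpochedData
from .montage import neighbor_table

__all__ = [
    "resample",
    "bandpass_notch",
    "BadChannel",
    "detect_bad_channels",
    "interpolate_spherical",
    "rereference_average",
    "reject_artifact_windows",
    "epoch",
    "preprocess_recording",
    "PreprocessReport",
]


def resample(recording: EEGRecording, target_rate: float) -> EEGRecording:
    """Polyphase anti-aliased resampling to ``target_rate`` Hz."""
    if target_rate <= 0:
        raise ValueError("target rate must be positive")
    if target_rate > recording.sampling_rate:
        raise ValueError("upsampling not supported; target_rate must be <= current rate")
    if target_rate == recording.sampling_rate:
        return recording.copy_with(recording.data.copy(), f"resample({target_rate})")
    frac = Fraction(target_rate).limit_denominator(10000) / Fraction(
        recording.sampling_rate
    ).limit_denominator(10000)
    up, down = frac.numerator, frac.denominator
    out = scipy.signal.resample_poly(recording.data, up, down, axis=1)
    n_new = int(np.floor(recording.n_samples * target_rate / recording.sampling_rate))
    out = out[:, :n_new]
    return recording.copy_with(out, f"resample({target_rate})", sampling_rate=float(target_rate))


def _fir_bandpass(low: float, high: float, fs: float, trans_bw: float = 1.0) -> np.ndarray:
    """Zero-phase-ready Hamming-windowed sinc band-pass kernel."""
    numtaps = int(np.ceil(3.3 / (trans_bw / fs)))
    numtaps |= 1  # odd length, linear phase type I
    return scipy.signal.firwin(numtaps, [low, high], pass_zero=False, window="hamming", fs=fs)


def bandpass_notch(
    recording: EEGRecording,
    low: float = 1.0,
    high: float = 40.0,
    notch: float = 50.0,
) -> EEGRecording:
    """Zero-phase 1-40 Hz band-pass followed by a 50 Hz notch; DC removed."""
    fs = recording.sampling_rate
    if not 0 < low < high < fs / 2:
        raise ValueError(f"band ({low}, {high}) invalid for sampling rate {fs}")
    data = recording.data - recording.data.mean(axis=1, keepdims=True)
    taps = _fir_bandpass(low, high, fs)
    padlen = min(3 * len(taps), data.shape[1] - 1)
    data = scipy.signal.filtfilt(taps, [1.0], data, axis=1, padlen=padlen)
    if notch and notch < fs / 2:
        b, a = scipy.signal.iirnotch(notch, Q=notch / 2.0, fs=fs)  # 2 Hz notch width
        data = scipy.signal.filtfilt(b, a, data, axis=1)
    return recording.copy_with(data, f"bandpass_notch({low}-{high}, notch={notch})")


@dataclass
class BadChannel:
    name: str
    reasons: list[str]


def _robust_sd(x: np.ndarray, axis=None) -> np.ndarray:
    """Median absolute deviation scaled to the SD of a Gaussian."""
    med = np.median(x, axis=axis, keepdims=True)
    return 1.4826 * np.median(np.abs(x - med), axis=axis)


def detect_bad_channels(
    recording: EEGRecording,
    flatline_s: float = 5.0,
    noise_sd: float = 4.0,
    min_corr: float = 0.8,
) -> list[BadChannel]:
    """Flag flatlined, excessively noisy and spatially decorrelated channels.

    Criteria (union; each flagged channel carries its reasons):

    - ``flatline``: any constant run (successive |diff| < 1e-10 uV) lasting
      at least ``flatline_s`` seconds;
    - ``noise``: the channel's robust high-frequency noise level (MAD-scaled
      SD of the first difference) is more than ``noise_sd`` robust SDs above
      the cross-channel median;
    - ``correlation``: over 1-s windows, the Pearson correlation between the
      channel and its spherical-spline prediction from all other good
      channels (leave-one-out) falls below ``min_corr`` in the majority of
      windows. Correlations are computed on a band-limited (1-20 Hz) copy
      and disattenuated for the channel's own sensor-noise floor, estimated
      from the signal-free high-frequency band (white-noise assumption);
      windows where the channel carries less signal than noise count as
      failing, since they cannot demonstrate spatial consistency.

    Raises ``ValueError`` if fewer than 4 channels survive.
    """
    fs = recording.sampling_rate
    n_ch, n_samp = recording.data.shape
    if n_samp < flatline_s * fs:
        raise ValueError("recording shorter than the flatline criterion window")
    reasons: dict[int, list[str]] = {}

    # -- flatline
    flat_run = int(np.ceil(flatline_s * fs))
    small = np.abs(np.diff(recording.data, axis=1)) < 1e-10
    for c in range(n_ch):
        padded = np.diff(np.concatenate(([0], small[c].astype(np.int8), [0])))
        starts = np.nonzero(padded == 1)[0]
        if starts.size:
            ends = np.nonzero(padded == -1)[0]
            # a run of R small diffs spans R+1 constant samples
            if int((ends - starts).max()) + 1 >= flat_run:
                reasons.setdefault(c, []).append("flatline")

    # -- noise level (MAD-based; the spread is floored at 5% of the median
    # level so near-identical channel noise cannot inflate the z-scores)
    noise = _robust_sd(np.diff(recording.data, axis=1), axis=1)
    center = np.median(noise)
    spread = max(1.4826 * np.median(np.abs(noise - center)), 0.05 * center)
    if spread > 0:
        z = (noise - center) / spread
        for c in np.nonzero(z > noise_sd)[0]:
            reasons.setdefault(int(c), []).append("noise")

    # -- spatial-prediction correlation over 1-s windows
    win = int(fs)
    n_win = n_samp // win
    if n_win >= 1:
        if fs > 60:
            sos = scipy.signal.butter(
                4, [1.0, min(20.0, fs / 2 - 1)], btype="bandpass", fs=fs, output="sos"
            )
            banded = scipy.signal.sosfiltfilt(sos, recording.data, axis=1)
            corr_bw = min(20.0, fs / 2 - 1) - 1.0
        else:
            banded = recording.data
            corr_bw = 0.0
        # per-channel white-noise floor from the band above the EEG signal
        noise_var_band = np.zeros(n_ch)
        if fs / 2 > 55.0 and corr_bw > 0:
            sos_hf = scipy.signal.butter(4, 50.0, btype="highpass", fs=fs, output="sos")
            hf = scipy.signal.sosfiltfilt(sos_hf, recording.data, axis=1)
            hf_bw = fs / 2 - 50.0
            noise_var_band = hf.var(axis=1) * (corr_bw / hf_bw)
        flagged = set(reasons)
        pred = np.zeros_like(banded)
        P = recording.channel_positions
        for c in range(n_ch):
            donors = [j for j in range(n_ch) if j != c and j not in flagged]
            if not donors:
                donors = [j for j in range(n_ch) if j != c]
            M = spherical_interpolation_matrix(P[donors], P[[c]])
            pred[c] = (M @ banded[donors])[0]
        bad_frac = np.zeros(n_ch)
        for k in range(n_win):
            seg = slice(k * win, (k + 1) * win)
            x = banded[:, seg]
            y = pred[:, seg]
            xc = x - x.mean(axis=1, keepdims=True)
            yc = y - y.mean(axis=1, keepdims=True)
            var_x = (xc**2).mean(axis=1)
            denom = np.linalg.norm(xc, axis=1) * np.linalg.norm(yc, axis=1)
            r = np.where(denom > 0, (xc * yc).sum(axis=1) / np.maximum(denom, 1e-30), 0.0)
            signal_var = var_x - noise_var_band
            uninformative = signal_var < noise_var_band  # in-window SNR < 1
            atten = np.sqrt(np.clip(signal_var / np.maximum(var_x, 1e-30), 0.05, 1.0))
            r_adj = np.clip(r / atten, -1.0, 1.0)
            bad_frac += uninformative | (r_adj < min_corr)
        bad_frac /= n_win
        for c in np.nonzero(bad_frac > 0.5)[0]:
            reasons.setdefault(int(c), []).append("correlation")

    flagged = [BadChannel(recording.channel_names[c], rs) for c, rs in sorted(reasons.items())]
    if n_ch - len(flagged) < 4:
        raise ValueError("fewer than 4 good channels remain; recording unusable")
    return flagged


def _spline_g(cosang: np.ndarray, m: int = 4, n_terms: int = 50) -> np.ndarray:
    """Perrin spherical-spline kernel g(cos angle), stiffness m."""
    n = np.arange(1, n_terms + 1)
    coef = (2 * n + 1) / (n * (n + 1.0)) ** m
    x = np.clip(cosang, -1.0, 1.0)
    P = np.stack([eval_legendre(k, x) for k in n])
    return (coef[:, None, None] * P).sum(axis=0) / (4.0 * np.pi)


def spherical_interpolation_matrix(
    pos_good: np.ndarray, pos_bad: np.ndarray, reg: float = 1e-5, m: int = 4
) -> np.ndarray:
    """Linear operator mapping good-channel values to bad-channel estimates.

    Spherical-spline interpolation: fits g-kernel weights plus a constant on
    the good electrodes (Tikhonov-regularised), then evaluates the smooth
    field at the bad electrode positions.
    """
    G = _spline_g(pos_good @ pos_good.T, m=m)
    Gb = _spline_g(pos_bad @ pos_good.T, m=m)
    n = len(pos_good)
    A = np.zeros((n + 1, n + 1))
    A[:n, :n] = G + reg * np.eye(n)
    A[:n, n] = 1.0
    A[n, :n] = 1.0
    # Solve [G+regI, 1; 1^T, 0] [w; c] = [v; 0] for each time sample; the
    # bad-channel estimate is Gb w + c, i.e. a fixed matrix applied to v.
    Ainv = np.linalg.inv(A)
    B = np.hstack([Gb, np.ones((len(pos_bad), 1))])
    return B @ Ainv[:, :n]


def interpolate_spherical(
    recording: EEGRecording, bad_channels: list[str] | list[BadChannel]
) -> EEGRecording:
    """Rebuild flagged channels by spherical-spline interpolation.

    Good channels pass through untouched; each bad channel becomes a fixed
    (time-independent) linear combination of the good channels.
    """
    names = [b.name if isinstance(b, BadChannel) else b for b in bad_channels]
    if not names:
        return recording.copy_with(recording.data.copy(), "interpolate_spherical([])")
    unknown = set(names) - set(recording.channel_names)
    if unknown:
        raise ValueError(f"unknown channels: {sorted(unknown)}")
    bad_idx = [recording.channel_names.index(n) for n in names]
    good_idx = [i for i in range(recording.n_channels) if i not in bad_idx]
    if not good_idx:
        raise ValueError("cannot interpolate: all channels bad")
    M = spherical_interpolation_matrix(
        recording.channel_positions[good_idx], recording.channel_positions[bad_idx]
    )
    data = recording.data.copy()
    data[bad_idx] = M @ recording.data[good_idx]
    return recording.copy_with(data, f"interpolate_spherical({names})")


def rereference_average(recording: EEGRecording) -> EEGRecording:
    """Subtract the instantaneous cross-channel mean from every sample."""
    data = recording.data - recording.data.mean(axis=0, keepdims=True)
    return recording.copy_with(data, "rereference_average")


def reject_artifact_windows(
    recording: EEGRecording,
    window_s: float = 0.5,
    sd_cut: float = 20.0,
) -> tuple[EEGRecording, list[tuple[int, int]]]:
    """Excise 0.5-s windows whose worst-channel RMS exceeds ``sd_cut`` x a
    calibration level estimated from the cleanest quartile of windows.

    Returns the cleaned recording (windows removed, cut points recorded in
    ``boundaries`` so later epoching never spans one) and the list of
    removed (start, end) sample spans in the input's time base.
    """
    fs = recording.sampling_rate
    win = int(round(window_s * fs))
    if recording.n_samples < win:
        raise ValueError("recording shorter than one artifact window")
    n_win = recording.n_samples // win
    segs = recording.data[:, : n_win * win].reshape(recording.n_channels, n_win, win)
    rms = np.sqrt((segs**2).mean(axis=2))  # (channels, windows)

    # per-channel calibration RMS: mean over that channel's cleanest quartile
    q = max(1, n_win // 4)
    calib = np.sort(rms, axis=1)[:, :q].mean(axis=1)
    calib = np.maximum(calib, 1e-12)
    bad = (rms / calib[:, None] > sd_cut).any(axis=0)

    if bad.mean() > 0.5:
        raise ValueError("more than half of all windows rejected; recording unusable")
    if not bad.any():
        return recording.copy_with(recording.data.copy(), "reject_artifact_windows[none]"), []

    mask: list[tuple[int, int]] = []
    for k in np.nonzero(bad)[0]:
        start, end = int(k) * win, (int(k) + 1) * win
        if mask and mask[-1][1] == start:
            mask[-1] = (mask[-1][0], end)
        else:
            mask.append((start, end))
    keep = np.ones(recording.n_samples, dtype=bool)
    for s, e in mask:
        keep[s:e] = False
    boundaries = []
    removed = 0
    for s, e in mask:
        cut = s - removed
        if 0 < cut < keep.sum():
            boundaries.append(cut)
        removed += e - s
    out = recording.copy_with(recording.data[:, keep], f"reject_artifact_windows[{len(mask)} spans]")
    out.boundaries = sorted(set(recording.boundaries) | set(boundaries))
    return out, mask


def epoch(recording: EEGRecording, epoch_s: float = 2.0) -> EpochedData:
    """Cut the cleaned continuous data into non-overlapping fixed epochs.

    Epoching restarts at every discontinuity boundary, so no epoch spans a
    cut; trailing remainders shorter than ``epoch_s`` are discarded.
    """
    fs = recording.sampling_rate
    n_per = int(round(epoch_s * fs))
    edges = [0, *recording.boundaries, recording.n_samples]
    chunks = []
    for a, b in zip(edges[:-1], edges[1:]):
        for k in range((b - a) // n_per):
            chunks.append(recording.data[:, a + k * n_per : a + (k + 1) * n_per])
    if not chunks:
        raise ValueError("no full epochs could be produced")
    return EpochedData(
        epochs=np.stack(chunks),
        epoch_length=epoch_s,
        sampling_rate=fs,
        channel_names=list(recording.channel_names),
    )


@dataclass
class PreprocessReport:
    """Structured log of one subject's preprocessing."""

    bad_channels: list[BadChannel] = field(default_factory=list)
    bad_channel_pct: float = 0.0
    rejected_windows: list[tuple[int, int]] = field(default_factory=list)
    rejected_pct: float = 0.0
    n_epochs: int = 0


def preprocess_recording(
    recording: EEGRecording,
    target_rate: float = 250.0,
    low: float = 1.0,
    high: float = 40.0,
    notch: float = 50.0,
    flatline_s: float = 5.0,
    noise_sd: float = 4.0,
    min_corr: float = 0.8,
    window_s: float = 0.5,
    sd_cut: float = 20.0,
    epoch_s: float = 2.0,
) -> tuple[EpochedData, PreprocessReport]:
    """Run the full chain in the fixed order and return epochs + report.

    Bad-channel detection inspects the resampled but *unfiltered* data:
    the flatline criterion needs exact constancy (a 6-s flat span is
    smeared by the seconds-long zero-phase FIR kernel) and the correlation
    criterion estimates each channel's sensor-noise floor from the >50 Hz
    band, which filtering empties. Interpolation then repairs the filtered
    data.
    """
    rec0 = resample(recording, target_rate)
    rec = bandpass_notch(rec0, low=low, high=high, notch=notch)
    bads = detect_bad_channels(rec0, flatline_s=flatline_s, noise_sd=noise_sd, min_corr=min_corr)
    rec = interpolate_spherical(rec, bads)
    rec = rereference_average(rec)
    total = rec.n_samples
    rec, mask = reject_artifact_windows(rec, window_s=window_s, sd_cut=sd_cut)
    epochs = epoch(rec, epoch_s=epoch_s)
    report = PreprocessReport(
        bad_channels=bads,
        bad_channel_pct=100.0 * len(bads) / recording.n_channels,
        rejected_windows=mask,
        rejected_pct=100.0 * sum(e - s for s, e in mask) / total,
        n_epochs=epochs.n_epochs,
    )
    return epochs, report
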