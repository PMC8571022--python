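import numpy as np
import pytest

import eegstates as es
from eegstates.containers import EEGRecording
from eegstates.montage import channel_positions, default_channels
from eegstates.preprocess import (
    bandpass_notch,
    detect_bad_channels,
    epoch,
    interpolate_spherical,
    reject_artifact_windows,
    rereference_average,
    resample,
    spherical_interpolation_matrix,
)


def _sine_recording(freqs, fs=1000.0, duration=10.0, n_channels=8):
    t = np.arange(int(duration * fs)) / fs
    data = np.array([10.0 * np.sin(2 * np.pi * f * t) for f in freqs])
    names = list(default_channels(n_channels))[: len(freqs)]
    return EEGRecording(
        data=data,
        sampling_rate=fs,
        channel_names=names,
        channel_positions=channel_positions(names),
    )


class TestResample:
    def test_1000_to_250_sample_count(self):
        rec = _sine_recording([5.0, 7.0], fs=1000.0, duration=5.0)
        out = resample(rec, 250.0)
        assert out.sampling_rate == 250.0
        assert out.n_samples == 1250

    def test_identity_at_same_rate(self, small_recording):
        rec, _, _ = small_recording
        out = resample(rec, rec.sampling_rate)
        np.testing.assert_allclose(out.data, rec.data, atol=1e-9)

    def test_sine_preserved_against_analytic_resampling(self):
        rec = _sine_recording([5.0], fs=1000.0, duration=10.0)
        out = resample(rec, 250.0)
        t = np.arange(out.n_samples) / 250.0
        ref = 10.0 * np.sin(2 * np.pi * 5.0 * t)
        r = np.corrcoef(out.data[0], ref)[0, 1]
        assert r >= 0.999

    def test_upsampling_rejected(self, small_recording):
        rec, _, _ = small_recording
        with pytest.raises(ValueError):
            resample(rec, 2 * rec.sampling_rate)


class TestBandpassNotch:
    def test_50hz_attenuated_10hz_passed_dc_removed(self):
        rec = _sine_recording([50.0, 10.0], fs=250.0, duration=20.0)
        rec.data = np.vstack([rec.data, np.full(rec.n_samples, 7.0)])
        rec.channel_names = list(default_channels(3))
        rec.channel_positions = channel_positions(rec.channel_names)
        out = bandpass_notch(rec, 1.0, 40.0, 50.0)
        rms_in = np.sqrt((rec.data[0] ** 2).mean())
        inner = slice(500, -500)  # ignore filter edge transients
        assert np.sqrt((out.data[0, inner] ** 2).mean()) <= 0.05 * rms_in
        assert np.sqrt((out.data[1, inner] ** 2).mean()) >= 0.90 * rms_in
        assert np.sqrt((out.data[2, inner] ** 2).mean()) <= 1e-6 * 7.0

    def test_invalid_band_rejected(self, small_recording):
        rec, _, _ = small_recording
        with pytest.raises(ValueError):
            bandpass_notch(rec, 40.0, 1.0)


class TestDetectBadChannels:
    def test_clean_recording_empty(self, small_recording):
        rec, _, _ = small_recording
        assert detect_bad_channels(rec) == []

    def test_flat_channel_flagged(self, small_recording):
        rec, _, _ = small_recording
        bad = es.inject_artifacts(rec, flat_channel_spec=[es.ArtifactSpec("Cz", 5.0, 11.0)])
        flagged = {b.name: b.reasons for b in detect_bad_channels(bad)}
        assert "Cz" in flagged and "flatline" in flagged["Cz"]

    def test_five_second_flat_span_is_the_threshold(self, small_recording):
        rec, _, _ = small_recording
        shorter = es.inject_artifacts(rec, flat_channel_spec=[es.ArtifactSpec("Cz", 5.0, 9.0)])
        names = [b.name for b in detect_bad_channels(shorter)]
        assert "Cz" not in names  # 4 s < 5 s criterion

    def test_decorrelated_channel_flagged(self, small_recording):
        rec, _, _ = small_recording
        bad = es.inject_artifacts(
            rec, noisy_channel_spec=[es.ArtifactSpec("C3", 0.0, 20.0, 1.0)], seed=4
        )
        flagged = {b.name: b.reasons for b in detect_bad_channels(bad)}
        assert "C3" in flagged and "correlation" in flagged["C3"]

    def test_too_few_good_channels_raises(self):
        rng = np.random.default_rng(0)
        names = list(default_channels(5))
        data = np.ones((5, 2000))
        data[0] = rng.normal(size=2000)
        rec = EEGRecording(
            data=data, sampling_rate=250.0, channel_names=names,
            channel_positions=channel_positions(names),
        )
        with pytest.raises(ValueError, match="unusable|good channels"):
            detect_bad_channels(rec, flatline_s=5.0)


class TestSphericalInterpolation:
    def test_no_bad_channels_identity(self, small_recording):
        rec, _, _ = small_recording
        out = interpolate_spherical(rec, [])
        np.testing.assert_array_equal(out.data, rec.data)

    def test_linear_field_recovered(self):
        # potential linear in position is maximally smooth: the spline
        # estimate at a left-out electrode must be within 5% of truth
        names = list(default_channels(64))
        P = channel_positions(names)
        field = 40.0 * (P @ np.array([0.3, 0.8, 0.52]))
        data = np.tile(field[:, None], (1, 10))
        rec = EEGRecording(
            data=data, sampling_rate=250.0, channel_names=names, channel_positions=P
        )
        out = interpolate_spherical(rec, ["Cz", "P3"])
        for name in ("Cz", "P3"):
            i = names.index(name)
            assert out.data[i, 0] == pytest.approx(field[i], rel=0.05)

    def test_interpolated_channel_is_fixed_linear_combination(self, small_recording):
        rec, _, _ = small_recording
        out = interpolate_spherical(rec, ["Fz"])
        i = rec.channel_names.index("Fz")
        good = [j for j in range(rec.n_channels) if j != i]
        w, *_ = np.linalg.lstsq(rec.data[good, :500].T, out.data[i, :500], rcond=None)
        np.testing.assert_allclose(out.data[i], w @ rec.data[good], atol=1e-8)

    def test_good_channels_untouched(self, small_recording):
        rec, _, _ = small_recording
        out = interpolate_spherical(rec, ["Fz"])
        i = rec.channel_names.index("Fz")
        good = [j for j in range(rec.n_channels) if j != i]
        np.testing.assert_array_equal(out.data[good], rec.data[good])

    def test_matches_mne_interpolation_operator(self):
        # independent cross-check against mne's spherical-spline matrix
        from mne.channels.interpolation import _make_interpolation_matrix

        P = channel_positions(default_channels(32))
        ours = spherical_interpolation_matrix(P[4:], P[:4])
        theirs = _make_interpolation_matrix(P[4:], P[:4])
        rng = np.random.default_rng(0)
        field = rng.normal(size=(28, 5))
        np.testing.assert_allclose(ours @ field, theirs @ field, atol=5e-3)


class TestAverageReference:
    def test_offset_removed_and_idempotent(self, small_recording):
        rec, _, _ = small_recording
        shifted = rec.copy_with(rec.data + 10.0, "shift")
        out = rereference_average(shifted)
        np.testing.assert_allclose(out.data.mean(axis=0), 0, atol=1e-9)
        again = rereference_average(out)
        np.testing.assert_allclose(again.data, out.data, atol=1e-9)


class TestRejectWindows:
    def test_clean_recording_empty_mask(self, small_recording):
        rec, _, _ = small_recording
        _, mask = reject_artifact_windows(rec)
        assert mask == []

    def test_burst_window_excised_exactly(self, small_recording):
        rec, _, _ = small_recording
        amp = 100.0 * np.std(rec.data)
        bad = es.inject_artifacts(rec, burst_spec=[es.ArtifactSpec("Cz", 4.0, 4.5, amp)])
        out, mask = reject_artifact_windows(bad)
        assert mask == [(1000, 1125)]
        assert out.n_samples == rec.n_samples - 125
        assert out.boundaries == [1000]

    def test_infinite_cut_is_identity(self, small_recording):
        rec, _, _ = small_recording
        out, mask = reject_artifact_windows(rec, sd_cut=np.inf)
        assert mask == []
        np.testing.assert_array_equal(out.data, rec.data)

    def test_mostly_bad_recording_rejected(self, small_recording):
        rec, _, _ = small_recording
        loud = rec.copy_with(rec.data.copy(), "loud")
        loud.data[:, : loud.n_samples * 3 // 4] *= 1e4
        with pytest.raises(ValueError, match="unusable"):
            reject_artifact_windows(loud)


class TestEpoch:
    def test_epoch_arithmetic(self, small_recording):
        rec, _, _ = small_recording  # 20 s at 250 Hz
        ep = epoch(rec, 2.0)
        assert ep.n_epochs == 10
        assert ep.epochs.shape == (10, 16, 500)

    def test_remainder_discarded(self, small_recording):
        rec, _, _ = small_recording
        short = rec.copy_with(rec.data[:, : int(5.5 * 250)], "crop")
        ep = epoch(short, 2.0)
        assert ep.n_epochs == 2

    def test_no_epoch_spans_a_cut(self, small_recording):
        rec, _, _ = small_recording
        amp = 100.0 * np.std(rec.data)
        bad = es.inject_artifacts(rec, burst_spec=[es.ArtifactSpec("Cz", 3.0, 3.5, amp)])
        cleaned, _ = reject_artifact_windows(bad)
        ep = epoch(cleaned, 2.0)
        # chunks: 3.0 s -> 1 epoch, 16.5 s -> 8 epochs
        assert ep.n_epochs == 9

    def test_signal_preserving_chain(self, noise_free_subject):
        # the full chain keeps the bulk of the topographic variance aligned
        # with the generating maps: the GFP^2-weighted explained variance of
        # the true labelling stays high. (Per-sample correlations cannot be
        # perfect: the synthetic signal is not band-limited, so the 1-40 Hz
        # zero-phase filter necessarily blends neighbouring segments.)
        from eegstates.maps import gev

        rec, gt, cfg = noise_free_subject
        epochs, report = es.preprocess_recording(rec, target_rate=250.0)
        assert report.bad_channels == []
        n_per = epochs.epochs.shape[2]
        V, labels, g = [], [], []
        for k, ep in enumerate(epochs.epochs):
            centered = ep - ep.mean(axis=0)
            V.append(centered.T)
            labels.append(gt.label_sequence[k * n_per : (k + 1) * n_per])
            g.append(np.linalg.norm(centered, axis=0) / np.sqrt(rec.n_channels))
        total, _ = gev(np.concatenate(V), np.concatenate(labels),
                       gt.templates, np.concatenate(g))
        assert total >= 0.85
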