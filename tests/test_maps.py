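import itertools

import numpy as np
import pytest

import eegstates as es
from eegstates.containers import EpochedData, GfpSeries, TemplateSet
from eegstates.maps import (
    aahc_cluster,
    align_subject_maps,
    canonical_archetypes,
    find_gfp_peaks,
    gev,
    gfp,
    group_mean_templates,
    label_canonical,
    peak_maps,
    spatial_correlation,
    subject_templates,
)

from .oracles import naive_aahc, naive_gev, partitions_equal


def _epochs_from(arrays, fs=250.0):
    return EpochedData(
        epochs=np.array(arrays),
        epoch_length=arrays[0].shape[1] / fs,
        sampling_rate=fs,
        channel_names=[f"ch{i}" for i in range(arrays[0].shape[0])],
    )


class TestGfp:
    @pytest.mark.parametrize(
        "map_, expected",
        [([1.0, -1.0], 1.0), ([5.0, 5.0, 5.0, 5.0], 0.0), ([2.0, 0.0, -2.0, 0.0], np.sqrt(2))],
    )
    def test_closed_form_values(self, map_, expected):
        ep = _epochs_from([np.array(map_)[:, None]], fs=1.0)
        series = gfp(ep)
        assert series.values[0][0] == pytest.approx(expected, abs=1e-12)

    def test_single_channel_rejected(self):
        with pytest.raises(ValueError):
            gfp(_epochs_from([np.ones((1, 10))]))


class TestGfpPeaks:
    def test_monotone_ramp_has_no_peaks(self):
        s = GfpSeries(values=[np.arange(100.0)], sampling_rate=250.0)
        assert len(find_gfp_peaks(s).peak_indices[0]) == 0

    def test_rectified_sinusoid_peak_rate(self):
        # |sin| at 10 Hz has 20 maxima per second
        t = np.arange(250 * 4) / 250.0
        s = GfpSeries(values=[np.abs(np.sin(2 * np.pi * 10 * t))], sampling_rate=250.0)
        n = len(find_gfp_peaks(s, min_distance_ms=10.0).peak_indices[0])
        assert abs(n / 4.0 - 20.0) <= 1.0

    def test_equal_maxima_within_distance_keep_earlier(self):
        v = np.zeros(50)
        v[[10, 11]] = [1.0, 0.5]
        v[13] = 1.0
        v[14] = 0.5
        s = GfpSeries(values=[v], sampling_rate=1000.0)  # 10 ms = 10 samples
        peaks = find_gfp_peaks(s, min_distance_ms=10.0).peak_indices[0]
        assert list(peaks) == [10]

    def test_boundary_samples_never_peaks(self):
        v = np.array([5.0, 1.0, 0.5, 1.0, 4.0])
        s = GfpSeries(values=[v], sampling_rate=250.0)
        peaks = find_gfp_peaks(s, min_distance_ms=0.0).peak_indices[0]
        assert 0 not in peaks and len(v) - 1 not in peaks


class TestSpatialCorrelation:
    def test_identity_and_polarity(self):
        u = np.array([1.0, -2.0, 0.5, 0.5])
        assert spatial_correlation(u, u) == pytest.approx(1.0)
        assert spatial_correlation(u, -u) == pytest.approx(1.0)
        assert spatial_correlation(u, -u, ignore_polarity=False) == pytest.approx(-1.0)

    def test_orthogonal_maps(self):
        assert spatial_correlation(
            np.array([1.0, -1.0, 0.0, 0.0]), np.array([0.0, 0.0, 1.0, -1.0])
        ) == pytest.approx(0.0, abs=1e-12)

    def test_constant_map_rejected(self):
        with pytest.raises(ValueError):
            spatial_correlation(np.ones(4), np.array([1.0, 2.0, 3.0, 4.0]))


class TestAahc:
    def test_noise_free_two_group_separation(self):
        a = np.array([1.0, -1.0, 0.0, 0.0])
        b = np.array([0.0, 0.0, 1.0, -1.0])
        maps = np.array([2 * a, -0.5 * a, 1.3 * a, b, -2 * b, 0.7 * b])
        ts, assign = aahc_cluster(maps, k=2)
        assert partitions_equal(assign, np.array([0, 0, 0, 1, 1, 1]))
        for t in ts.maps:
            assert max(
                spatial_correlation(t, a), spatial_correlation(t, b)
            ) == pytest.approx(1.0, abs=1e-9)

    def test_k_equals_n_gives_gev_one(self):
        rng = np.random.default_rng(0)
        maps = rng.normal(size=(7, 6))
        ts, assign = aahc_cluster(maps, k=7)
        assert sorted(assign) == list(range(7))
        assert ts.gev_total == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_naive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(12, 40))
        maps = rng.normal(size=(n, 8))
        _, ours = aahc_cluster(maps, k=3)
        theirs = naive_aahc(maps, k=3)
        assert partitions_equal(ours, theirs)

    def test_invariant_to_scale_and_sign(self):
        rng = np.random.default_rng(5)
        maps = rng.normal(size=(20, 8))
        _, base = aahc_cluster(maps, k=3)
        scales = rng.uniform(0.5, 2.0, size=20) * rng.choice([-1, 1], size=20)
        _, scaled = aahc_cluster(maps * scales[:, None], k=3)
        assert partitions_equal(base, scaled)

    def test_gev_monotone_in_k(self):
        rng = np.random.default_rng(11)
        maps = rng.normal(size=(30, 8))
        gevs = [aahc_cluster(maps, k=k)[0].gev_total for k in (2, 3, 4, 6)]
        assert all(b >= a - 1e-12 for a, b in zip(gevs[:-1], gevs[1:]))


class TestGev:
    def test_perfect_labelling_gives_one(self):
        rng = np.random.default_rng(2)
        T = rng.normal(size=(3, 8))
        T -= T.mean(axis=1, keepdims=True)
        T /= np.linalg.norm(T, axis=1, keepdims=True)
        labels = np.array([0, 1, 2, 0, 1, 2])
        scales = np.array([1.0, -2.0, 0.5, 3.0, -1.0, 1.5])
        maps = T[labels] * scales[:, None]
        g = np.abs(scales) / np.sqrt(8)
        total, per = gev(maps, labels, T, g)
        assert total == pytest.approx(1.0, abs=1e-9)
        assert per.sum() == pytest.approx(total, abs=1e-9)

    def test_orthogonal_labelling_gives_zero(self):
        T = np.array([[1.0, -1.0, 0.0, 0.0], [0.0, 0.0, 1.0, -1.0]])
        maps = np.array([T[0], T[0]])
        total, _ = gev(maps, np.array([1, 1]), T, np.ones(2))
        assert total == pytest.approx(0.0, abs=1e-12)

    def test_backfit_labelling_beats_random(self):
        rng = np.random.default_rng(3)
        T = rng.normal(size=(4, 16))
        T -= T.mean(axis=1, keepdims=True)
        T /= np.linalg.norm(T, axis=1, keepdims=True)
        labels_true = rng.integers(0, 4, size=200)
        maps = T[labels_true] + 0.2 * rng.normal(size=(200, 16))
        g = np.linalg.norm(maps - maps.mean(1, keepdims=True), axis=1) / 4.0
        centered = maps - maps.mean(1, keepdims=True)
        best = np.argmax(np.abs(centered @ T.T), axis=1)
        g_best, _ = gev(maps, best, T, g)
        g_rand, _ = gev(maps, rng.integers(0, 4, 200), T, g)
        assert g_best > g_rand

    def test_matches_naive_oracle(self):
        rng = np.random.default_rng(9)
        T = rng.normal(size=(3, 8))
        maps = rng.normal(size=(25, 8))
        labels = rng.integers(0, 3, 25)
        g = rng.uniform(0.5, 2.0, 25)
        total, _ = gev(maps, labels, T, g)
        assert total == pytest.approx(naive_gev(maps, labels, T, g), abs=1e-12)


class TestAlignment:
    def _subject_sets(self, seed=0, n_subjects=5):
        M = es.make_template_maps(16, 4, seed=seed, min_separation=0.5)
        rng = np.random.default_rng(seed + 1)
        sets = []
        for s in range(n_subjects):
            perm = rng.permutation(4)
            signs = rng.choice([-1.0, 1.0], size=4)
            sets.append(
                TemplateSet(maps=M[perm] * signs[:, None],
                            channel_names=[f"ch{i}" for i in range(16)],
                            source=f"s{s}")
            )
        return M, sets

    def test_shuffled_identical_subjects_recovered(self):
        M, sets = self._subject_sets()
        aligned, objective = align_subject_maps(sets)
        mean_ts = group_mean_templates(aligned)
        for j in range(4):
            assert max(
                spatial_correlation(mean_ts.maps[j], M[i]) for i in range(4)
            ) == pytest.approx(1.0, abs=1e-9)
        # all subjects end in the same order
        for ts in aligned[1:]:
            for j in range(4):
                assert spatial_correlation(ts.maps[j], aligned[0].maps[j]) == pytest.approx(
                    1.0, abs=1e-9
                )

    def test_objective_non_decreasing(self):
        M, sets = self._subject_sets(seed=4)
        rng = np.random.default_rng(99)
        noisy = [
            TemplateSet(
                maps=ts.maps + 0.15 * rng.normal(size=ts.maps.shape),
                channel_names=ts.channel_names,
            )
            for ts in sets
        ]
        _, objective = align_subject_maps(noisy)
        assert len(objective) <= 100
        assert all(b >= a - 1e-9 for a, b in zip(objective[:-1], objective[1:]))

    def test_single_subject_identity(self):
        M, sets = self._subject_sets(n_subjects=1)
        aligned, _ = align_subject_maps(sets[:1])
        np.testing.assert_array_equal(aligned[0].maps, sets[0].maps)

    def test_sign_flipped_pair_mean(self):
        M, _ = self._subject_sets()
        chans = [f"ch{i}" for i in range(16)]
        a = TemplateSet(maps=M, channel_names=chans)
        b = TemplateSet(maps=-M, channel_names=chans)
        mean_ts = group_mean_templates([a, b])
        for j in range(4):
            assert spatial_correlation(mean_ts.maps[j], M[j]) == pytest.approx(1.0, abs=1e-9)


class TestCanonicalLabelling:
    def test_archetypes_label_themselves(self):
        arch = canonical_archetypes(list(es.montage.default_channels(32)))
        out = label_canonical(arch)
        assert out.labels == ["A", "B", "C", "D"]

    def test_sign_flips_do_not_change_labels(self):
        arch = canonical_archetypes(list(es.montage.default_channels(32)))
        flipped = TemplateSet(
            maps=arch.maps * np.array([-1, 1, -1, 1])[:, None],
            channel_names=arch.channel_names,
        )
        assert label_canonical(flipped).labels == ["A", "B", "C", "D"]

    @pytest.mark.parametrize("perm", list(itertools.permutations(range(4)))[::5])
    def test_permutations_recovered(self, perm):
        arch = canonical_archetypes(list(es.montage.default_channels(32)))
        shuffled = TemplateSet(
            maps=arch.maps[list(perm)], channel_names=arch.channel_names
        )
        out = label_canonical(shuffled)
        assert out.labels == [["A", "B", "C", "D"][i] for i in perm]


class TestTemplateRecovery:
    def test_subject_templates_recover_generators(self, noise_free_subject):
        rec, gt, cfg = noise_free_subject
        epochs = es.epoch(es.rereference_average(rec), 2.0)
        ts = subject_templates(epochs, k=4)
        R = np.zeros((4, 4))
        for i in range(4):
            for j in range(4):
                R[i, j] = spatial_correlation(ts.maps[i], gt.templates[j])
        best = max(
            itertools.permutations(range(4)), key=lambda p: sum(R[i, p[i]] for i in range(4))
        )
        assert min(R[i, best[i]] for i in range(4)) >= 0.99
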