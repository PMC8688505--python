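"""Microstate estimation: GFP, modified k-means, back-fitting, parameters."""

import numpy as np
import pytest

from microdyn.containers import EEGRecording, LabelSequence
from microdyn.microstates import (
    MicrostateModel,
    align_maps_group,
    assign_canonical_names,
    backfit,
    gev,
    gfp,
    gfp_peaks,
    microstate_parameters,
    modified_kmeans,
    select_optimal_k,
    spatial_correlation,
)
from microdyn.synth import SynthConfig, make_template_maps, simulate_label_sequence

from conftest import make_recording


def match_maps(est: np.ndarray, true: np.ndarray) -> float:
    """Mean |corr| between estimated and true maps after optimal matching."""
    from scipy.optimize import linear_sum_assignment

    corr = np.abs(spatial_correlation(est, true))
    r, c = linear_sum_assignment(-corr)
    return corr[r, c].mean()


class TestGFP:
    def test_equal_potentials_zero(self):
        rec = make_recording(np.full((8, 10), 3.0))
        assert np.allclose(gfp(rec).values, 0.0)

    def test_two_channel_example(self):
        data = np.array([[2.0], [-2.0]] * 4)  # 8 channels alternating +-2
        rec = make_recording(data)
        assert gfp(rec).values[0] == pytest.approx(2.0)

    def test_common_offset_invariance(self):
        rng = np.random.default_rng(0)
        data = rng.standard_normal((8, 100))
        a = gfp(make_recording(data)).values
        b = gfp(make_recording(data + 5.0)).values
        assert np.allclose(a, b)

    def test_single_channel_rejected(self):
        with pytest.raises(ValueError):
            gfp(make_recording(np.ones((1, 10))))


class TestGFPPeaks:
    def test_monotone_series_no_peaks(self):
        from microdyn.microstates import GFPSeries

        s = GFPSeries(values=np.arange(100, dtype=float), fs=250.0)
        assert gfp_peaks(s).size == 0

    def test_alpha_modulated_rate(self):
        # |sin(2 pi 10 t)| has two maxima per cycle: ~20 peaks/s at fs 250
        t = np.arange(0, 10, 1 / 250)
        from microdyn.microstates import GFPSeries

        s = GFPSeries(values=np.abs(np.sin(2 * np.pi * 10 * t)), fs=250.0)
        rate = gfp_peaks(s).size / 10.0
        assert abs(rate - 20.0) <= 1.0

    def test_plateau_first_sample_only(self):
        from microdyn.microstates import GFPSeries

        v = np.array([0.0, 1.0, 1.0, 1.0, 0.0, 2.0, 0.0])
        s = GFPSeries(values=v, fs=100.0)
        assert list(gfp_peaks(s)) == [1, 5]


class TestModifiedKMeans:
    def test_noise_free_recovery(self, montage64):
        maps = make_template_maps(montage64, 5, seed=3)
        rng = np.random.default_rng(3)
        labels = rng.integers(0, 5, 600)
        amp = rng.uniform(5, 15, 600) * np.where(rng.random(600) < 0.5, 1, -1)
        x = maps.maps[labels] * amp[:, None]
        model = modified_kmeans(x, 5, n_restarts=10, seed=0)
        assert match_maps(model.maps, maps.maps) >= 0.999
        assert model.cost_f == pytest.approx(0.0, abs=1e-12)

    def test_polarity_invariance_of_fit(self, montage64):
        maps = make_template_maps(montage64, 4, seed=4)
        rng = np.random.default_rng(4)
        labels = rng.integers(0, 4, 400)
        x = maps.maps[labels] * rng.uniform(5, 15, 400)[:, None]
        x += 0.2 * rng.standard_normal(x.shape)
        x -= x.mean(axis=1, keepdims=True)
        a = modified_kmeans(x, 4, n_restarts=5, seed=1)
        b = modified_kmeans(-x, 4, n_restarts=5, seed=1)
        assert a.cost_f == pytest.approx(b.cost_f, rel=1e-9)
        assert match_maps(a.maps, b.maps) > 1 - 1e-9

    def test_cost_never_increases(self, montage64):
        maps = make_template_maps(montage64, 4, seed=5)
        rng = np.random.default_rng(5)
        x = maps.maps[rng.integers(0, 4, 500)] * rng.uniform(5, 15, 500)[:, None]
        x += rng.standard_normal(x.shape)
        model = modified_kmeans(x, 4, n_restarts=3, seed=2)
        assert np.all(np.diff(model.cost_history) <= 1e-9)

    def test_perfect_fit_zero_cv_residual(self, montage64):
        maps = make_template_maps(montage64, 3, seed=6)
        x = np.repeat(maps.maps, 50, axis=0) * 7.0
        model = modified_kmeans(x, 3, n_restarts=5, seed=3)
        assert model.cost_f == pytest.approx(0.0, abs=1e-12)
        assert model.cv == pytest.approx(0.0, abs=1e-12)


class TestSelectOptimalK:
    def test_recovers_planted_k(self, montage64):
        maps = make_template_maps(montage64, 5, seed=7)
        rng = np.random.default_rng(7)
        x = maps.maps[rng.integers(0, 5, 1500)] * rng.uniform(5, 15, 1500)[:, None]
        x += 0.05 * rng.standard_normal(x.shape)
        x -= x.mean(axis=1, keepdims=True)
        k_star, models = select_optimal_k(x, range(2, 9), n_restarts=10, seed=0)
        assert k_star == 5
        assert set(models) == set(range(2, 9))

    def test_cv_undefined_k_skipped(self):
        rng = np.random.default_rng(8)
        x = rng.standard_normal((200, 9))
        with pytest.warns(UserWarning):
            k_star, models = select_optimal_k(x, range(7, 10), n_restarts=2, seed=0)
        assert 8 not in models and 9 not in models


class TestGroupAlignment:
    def test_permuted_identical_maps_recovered(self, montage64):
        maps = make_template_maps(montage64, 7, seed=9)
        rng = np.random.default_rng(9)
        models = []
        perms_true = []
        for _ in range(4):
            perm = rng.permutation(7)
            signs = rng.choice([-1.0, 1.0], size=7)
            models.append(
                MicrostateModel(
                    maps=maps.maps[perm] * signs[:, None],
                    channel_labels=maps.channel_labels,
                )
            )
            perms_true.append(perm)
        group, perms = align_maps_group(models)
        for m, p in zip(models, perms):
            corr = np.abs(spatial_correlation(m.maps[p], group.maps))
            assert np.allclose(np.diag(corr), 1.0, atol=1e-9)

    def test_sign_flip_invariance(self, montage64):
        maps = make_template_maps(montage64, 4, seed=10)
        m1 = MicrostateModel(maps=maps.maps.copy(), channel_labels=maps.channel_labels)
        m2 = MicrostateModel(maps=-maps.maps.copy(), channel_labels=maps.channel_labels)
        group, perms = align_maps_group([m1, m2])
        assert all(np.array_equal(p, np.arange(4)) for p in perms)


class TestBackfit:
    def test_exact_map_assignment(self, montage64):
        maps = make_template_maps(montage64, 5, seed=11)
        data = np.tile(maps.maps[2], (100, 1)).T * 8.0
        rec = EEGRecording(
            data=data,
            fs=250.0,
            channel_labels=list(maps.channel_labels),
            positions=montage64.positions,
        )
        assert np.all(backfit(rec, maps).labels == 2)

    def test_polarity_ignored(self, montage64):
        maps = make_template_maps(montage64, 5, seed=11)
        data = -np.tile(maps.maps[2], (100, 1)).T * 8.0
        rec = EEGRecording(
            data=data,
            fs=250.0,
            channel_labels=list(maps.channel_labels),
            positions=montage64.positions,
        )
        assert np.all(backfit(rec, maps).labels == 2)

    def test_zero_gfp_carries_previous_label(self, montage64):
        maps = make_template_maps(montage64, 3, seed=12)
        data = np.column_stack([maps.maps[1] * 5, np.zeros(64), maps.maps[2] * 5])
        rec = EEGRecording(
            data=data,
            fs=250.0,
            channel_labels=list(maps.channel_labels),
            positions=montage64.positions,
        )
        assert list(backfit(rec, maps).labels) == [1, 1, 2]

    def test_noise_free_sequence_recovery(self, montage64):
        from microdyn.synth import simulate_eeg

        cfg = SynthConfig(n_channels=64, fs=250.0, k_true=5, snr=np.inf, seed=13)
        maps = make_template_maps(montage64, 5, seed=13)
        labels = simulate_label_sequence(cfg, 5000)
        rec = simulate_eeg(maps, labels, cfg, montage=montage64)
        fit = backfit(rec, maps)
        amp = np.abs(rec.data).max(axis=0)
        nonzero = amp > 1e-9
        assert np.array_equal(fit.labels[nonzero], labels.labels[nonzero])


class TestGEV:
    def test_perfect_fit_is_one(self, montage64):
        maps = make_template_maps(montage64, 4, seed=14)
        rng = np.random.default_rng(14)
        labels = rng.integers(0, 4, 300)
        x = maps.maps[labels] * rng.uniform(5, 15, 300)[:, None]
        model = MicrostateModel(maps=maps.maps, channel_labels=maps.channel_labels)
        assert gev(x, model, labels) == pytest.approx(1.0, abs=1e-12)

    def test_sign_flip_invariance(self, montage64):
        maps = make_template_maps(montage64, 4, seed=15)
        rng = np.random.default_rng(15)
        labels = rng.integers(0, 4, 300)
        x = maps.maps[labels] * rng.uniform(5, 15, 300)[:, None]
        x += rng.standard_normal(x.shape)
        m1 = MicrostateModel(maps=maps.maps.copy(), channel_labels=maps.channel_labels)
        flip = maps.maps.copy()
        flip[1] *= -1
        m2 = MicrostateModel(maps=flip, channel_labels=maps.channel_labels)
        assert gev(x, m1, labels) == pytest.approx(gev(x, m2, labels), abs=1e-12)

    def test_random_labels_orthogonal_maps_near_1_over_k(self):
        rng = np.random.default_rng(16)
        k, c, n = 4, 64, 20000
        q, _ = np.linalg.qr(rng.standard_normal((c, k)))
        maps = q.T - q.T.mean(axis=1, keepdims=True)
        maps /= np.linalg.norm(maps, axis=1, keepdims=True)
        model = MicrostateModel(maps=maps, channel_labels=[f"c{i}" for i in range(c)])
        x = rng.standard_normal((n, c))
        labels = rng.integers(0, k, n)
        g = gev(x, model, labels)
        assert abs(g - 1.0 / c) < 0.5 / c  # E[corr^2] = 1/(c-1) for random data


class TestMicrostateParameters:
    def test_direct_count_example(self):
        s = LabelSequence(np.array([0, 0, 1, 1, 1]), fs=5.0, n_classes=2)
        p = microstate_parameters(s)
        assert p.coverage[0] == pytest.approx(0.4)
        assert p.coverage[1] == pytest.approx(0.6)
        assert p.duration_ms[0] == pytest.approx(400.0)
        assert p.duration_ms[1] == pytest.approx(600.0)
        assert p.occurrence_hz[0] == pytest.approx(1.0)
        assert p.occurrence_hz[1] == pytest.approx(1.0)

    def test_constant_sequence(self):
        s = LabelSequence(np.zeros(500, dtype=int), fs=250.0, n_classes=2)
        p = microstate_parameters(s)
        assert p.coverage[0] == 1.0
        assert p.occurrence_hz[0] == pytest.approx(1.0 / 2.0)
        assert np.isnan(p.duration_ms[1])
        assert p.occurrence_hz[1] == 0.0

    def test_coverage_sums_to_one(self):
        rng = np.random.default_rng(17)
        s = LabelSequence(rng.integers(0, 7, 9999), fs=250.0, n_classes=7)
        p = microstate_parameters(s)
        assert p.coverage.sum() == pytest.approx(1.0, abs=1e-12)

    def test_planted_dwell_recovered(self):
        cfg = SynthConfig(k_true=7, fs=250.0, mean_duration_ms=50.0, seed=18)
        s = simulate_label_sequence(cfg, 100000)
        p = microstate_parameters(s)
        est = np.nansum(p.duration_ms * p.occurrence_hz) / p.occurrence_hz.sum()
        assert abs(est - 50.0) / 50.0 < 0.10


class TestCanonicalNaming:
    def test_names_are_unique_and_complete(self, montage64):
        maps = make_template_maps(montage64, 7, seed=19)
        names = assign_canonical_names(maps, montage64.positions)
        assert sorted(names) == ["A", "B", "C", "D", "E", "F", "G"]
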