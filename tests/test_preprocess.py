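"""Cleaning chain: filter, QC rules, interpolation, reference, resampling."""

import numpy as np
import pytest

from microdyn.containers import Annotation, EEGRecording
from microdyn.preprocess import (
    EpochedData,
    PreprocessConfig,
    average_reference,
    bandpass_fir,
    detect_bad_channels,
    downsample,
    epoch,
    faster_local_qc,
    reject_segments,
    run_preprocess,
    spherical_spline_interpolate,
)

from conftest import make_recording


def sine_recording(freq, fs=500.0, seconds=20.0, n_ch=8, amp=1.0):
    t = np.arange(0, seconds, 1 / fs)
    data = np.tile(amp * np.sin(2 * np.pi * freq * t), (n_ch, 1))
    return make_recording(data, fs=fs)


class TestBandpass:
    def test_slow_drift_removed(self):
        rec = sine_recording(0.1)
        out = bandpass_fir(rec, 1.0, 40.0)
        assert np.sqrt((out.data**2).mean()) < 0.05 * np.sqrt((rec.data**2).mean())

    def test_passband_amplitude_preserved(self):
        rec = sine_recording(10.0)
        out = bandpass_fir(rec, 1.0, 40.0)
        mid = slice(2000, 8000)  # avoid edges
        ratio = out.data[0, mid].std() / rec.data[0, mid].std()
        assert abs(ratio - 1.0) < 0.02

    def test_idempotent_within_ripple(self):
        rec = sine_recording(10.0)
        once = bandpass_fir(rec, 1.0, 40.0)
        twice = bandpass_fir(once, 1.0, 40.0)
        mid = slice(2000, 8000)
        assert np.abs(twice.data[:, mid] - once.data[:, mid]).max() < 0.02

    def test_short_record_rejected(self):
        rec = make_recording(np.zeros((8, 100)), fs=500.0)
        with pytest.raises(ValueError):
            bandpass_fir(rec, 1.0, 40.0)


class TestDetectBadChannels:
    def test_flat_channel_flagged(self, montage63):
        rng = np.random.default_rng(0)
        data = rng.standard_normal((63, 3500)) * 10  # 14 s at 250 Hz
        data[5] = 0.0  # flat throughout (> 5 s)
        rec = make_recording(data, fs=250.0, montage=montage63)
        rep = detect_bad_channels(rec)
        assert (montage63.channel_labels[5], "flat") in rep.bad_global_channels

    def test_decorrelated_channel_flagged(self, montage63):
        rng = np.random.default_rng(1)
        # smooth common field + small local noise -> high neighbor correlation
        common = rng.standard_normal(3000) * 10
        weights = 1 + 0.2 * rng.standard_normal(63)
        data = weights[:, None] * common + 0.5 * rng.standard_normal((63, 3000))
        data[7] = 10 * rng.standard_normal(3000)  # independent noise
        rec = make_recording(data, fs=250.0, montage=montage63)
        rep = detect_bad_channels(rec)
        lab = montage63.channel_labels[7]
        assert (lab, "correlation") in rep.bad_global_channels

    def test_iid_channels_never_amplitude_flagged(self, montage63):
        # per-channel RMS concentrates tightly around the pooled SD, so the
        # 3-pooled-SD amplitude rule fires on none of 20 iid trials
        rng = np.random.default_rng(2)
        for _ in range(20):
            rec = make_recording(rng.standard_normal((63, 2000)), fs=250.0, montage=montage63)
            rep = detect_bad_channels(rec)
            assert not any(c == "amplitude" for _, c in rep.bad_global_channels)

    def test_huge_amplitude_channel_flagged(self, montage63):
        rng = np.random.default_rng(3)
        common = rng.standard_normal(3000) * 10
        data = common + 0.5 * rng.standard_normal((63, 3000))
        data[3] *= 8.0
        rec = make_recording(data, fs=250.0, montage=montage63)
        rep = detect_bad_channels(rec)
        assert any(lab == montage63.channel_labels[3] for lab, _ in rep.bad_global_channels)


class TestEpoch:
    def test_exact_division(self):
        rec = make_recording(np.zeros((8, 2500)), fs=250.0)
        ep = epoch(rec, 2.0)
        assert ep.data.shape == (5, 8, 500)

    def test_remainder_dropped(self):
        rec = make_recording(np.zeros((8, 2475)), fs=250.0)  # 9.9 s
        ep = epoch(rec, 2.0)
        assert ep.n_epochs == 4

    def test_annotation_mapping(self):
        rec = make_recording(np.zeros((8, 2500)), fs=250.0)
        rec.annotations.append(Annotation(0.0, 4.0, "REST", "run1"))
        rec.annotations.append(Annotation(4.0, 6.0, "IG", "run1"))
        ep = epoch(rec, 2.0)
        assert ep.conditions == ["REST", "REST", "IG", "IG", "IG"]

    def test_too_short_record(self):
        rec = make_recording(np.zeros((8, 100)), fs=250.0)
        with pytest.raises(ValueError):
            epoch(rec, 2.0)


def gaussian_epochs(rng, n_ep=30, n_ch=63, n_per=500):
    data = rng.standard_normal((n_ep, n_ch, n_per))
    return EpochedData(
        data=data,
        fs=250.0,
        channel_labels=[f"E{i}" for i in range(n_ch)],
        positions=np.zeros((n_ch, 3)),
        conditions=[""] * n_ep,
        runs=[""] * n_ep,
    )


class TestFasterLocalQC:
    def test_scaled_channel_flagged_by_variance_and_range(self):
        rng = np.random.default_rng(4)
        ep = gaussian_epochs(rng)
        ep.data[10, 20] *= 20.0
        rep = faster_local_qc(ep)
        assert (10, "E20") in rep.interpolated_local

    def test_homogeneous_gaussian_false_flag_rate_low(self):
        # Monte-Carlo of the |Z|>3 rule on homogeneous data: the false-flag
        # rate per (epoch, channel) pair is ~1.7%; assert it stays below 4%
        rng = np.random.default_rng(5)
        pairs, total = 0, 0
        for _ in range(5):
            ep = gaussian_epochs(rng)
            rep = faster_local_qc(ep)
            pairs += len(rep.interpolated_local)
            total += ep.n_epochs * 63
        assert pairs / total < 0.04

    def test_needs_three_epochs(self):
        rng = np.random.default_rng(6)
        ep = gaussian_epochs(rng, n_ep=2)
        with pytest.raises(ValueError):
            faster_local_qc(ep)


class TestRejectSegments:
    def test_large_spike_rejected(self):
        rng = np.random.default_rng(7)
        ep = gaussian_epochs(rng, n_ch=16)
        ep.data *= 10.0  # ~10 uV RMS, well under 100 uV
        ep.data[4, 3, 100] = 150.0
        rep = reject_segments(ep)
        assert (4, "amplitude") in rep.bad_segments

    def test_clean_epochs_not_amplitude_rejected(self):
        rng = np.random.default_rng(8)
        ep = gaussian_epochs(rng, n_ch=16)
        ep.data = np.clip(ep.data * 10.0, -80, 80)
        rep = reject_segments(ep)
        assert not any(c == "amplitude" for _, c in rep.bad_segments)

    def test_variance_outlier_epoch_caught_by_probability(self):
        rng = np.random.default_rng(9)
        ep = gaussian_epochs(rng, n_ch=16)
        ep.data *= 10.0
        ep.data[12] = np.clip(ep.data[12] * 2.0, -95, 95)  # inflated, < 100 uV
        assert np.abs(ep.data).max() < 100
        rep = reject_segments(ep)
        assert 12 in {e for e, _ in rep.bad_segments}

    def test_all_rejected_raises(self):
        ep = gaussian_epochs(np.random.default_rng(10), n_ep=3, n_ch=8)
        ep.data[:] = 500.0
        with pytest.raises(RuntimeError):
            reject_segments(ep)


class TestSphericalSpline:
    def test_constant_field_reproduced(self, montage63):
        data = np.full((63, 50), 7.5)
        rec = make_recording(data, fs=250.0, montage=montage63)
        out = spherical_spline_interpolate(rec, [montage63.channel_labels[10]])
        assert np.allclose(out.data[10], 7.5, atol=1e-6)

    def test_smooth_dipolar_field_recovered(self, montage63):
        rng = np.random.default_rng(11)
        # dipolar potential: linear field plus mild curvature
        direction = np.array([0.3, 0.8, 0.52])
        base = montage63.positions @ direction
        t = rng.standard_normal(200)
        data = np.outer(base, t) + np.outer(base**2, 0.3 * t)
        rec = make_recording(data, fs=250.0, montage=montage63)
        target = montage63.channel_labels[20]
        out = spherical_spline_interpolate(rec, [target])
        corr = np.corrcoef(out.data[20], data[20])[0, 1]
        assert corr > 0.95

    def test_good_channels_untouched(self, montage63):
        rng = np.random.default_rng(12)
        data = rng.standard_normal((63, 40))
        rec = make_recording(data, fs=250.0, montage=montage63)
        out = spherical_spline_interpolate(rec, [montage63.channel_labels[0]])
        assert np.array_equal(out.data[1:], data[1:])

    def test_commutes_with_average_reference(self, montage63):
        rng = np.random.default_rng(13)
        common = rng.standard_normal(60)
        data = np.outer(montage63.positions @ np.array([0.1, 0.9, 0.42]), common)
        rec = make_recording(data, fs=250.0, montage=montage63)
        bad = [montage63.channel_labels[5]]
        a = average_reference(spherical_spline_interpolate(rec, bad))
        b = spherical_spline_interpolate(average_reference(rec), bad)
        # interpolation is linear and reference is a linear map: re-running
        # the reference after interpolation gives the same record
        assert np.allclose(average_reference(b).data, a.data, atol=1e-9)

    def test_too_many_bad_channels(self, montage63):
        rec = make_recording(np.zeros((63, 10)), fs=250.0, montage=montage63)
        with pytest.raises(ValueError):
            spherical_spline_interpolate(rec, list(montage63.channel_labels[:40]))


class TestReferenceAndResampling:
    def test_average_reference_zero_mean_and_idempotent(self):
        rng = np.random.default_rng(14)
        rec = make_recording(rng.standard_normal((16, 500)), fs=250.0)
        out = average_reference(rec)
        assert np.abs(out.data.mean(axis=0)).max() < 1e-9
        again = average_reference(out)
        assert np.allclose(again.data, out.data)
        assert out.reference == "average"

    def test_halved_sample_count(self):
        rec = make_recording(np.zeros((8, 1000)), fs=500.0)
        out = downsample(rec, 250.0)
        assert abs(out.n_samples - 500) <= 1
        assert out.fs == 250.0

    def test_sine_survives_downsampling(self):
        rec = sine_recording(10.0, fs=500.0, seconds=10.0)
        out = downsample(rec, 250.0)
        mid = slice(500, 2000)
        ratio = out.data[0, mid].std() / rec.data[0, 1000:4000].std()
        assert abs(ratio - 1.0) < 0.02

    def test_upsampling_rejected(self):
        rec = make_recording(np.zeros((8, 100)), fs=250.0)
        with pytest.raises(ValueError):
            downsample(rec, 500.0)


@pytest.fixture(scope="module")
def chain_result(montage63):
    from microdyn.synth import SynthConfig, make_template_maps, simulate_eeg, simulate_label_sequence

    cfg = SynthConfig(n_channels=63, fs=500.0, k_true=4, snr=2.0, seed=21)
    maps = make_template_maps(montage63, 4, seed=21)
    labels = simulate_label_sequence(cfg, 10000)  # 20 s
    rec = simulate_eeg(maps, labels, cfg, montage=montage63, condition="REST")
    out, report = run_preprocess(rec, PreprocessConfig())
    return rec, out, report


class TestFullChain:
    def test_output_rate_and_reference(self, chain_result):
        _, out, _ = chain_result
        assert out.fs == 250.0
        assert out.reference == "average"
        assert np.abs(out.data.mean(axis=0)).max() < 1e-9

    def test_provenance_conservation(self, chain_result):
        rec, out, report = chain_result
        n_epochs_in = int(rec.n_samples // (2.0 * rec.fs))
        n_dropped = len({e for e, _ in report.bad_segments})
        kept = n_epochs_in - n_dropped
        assert out.n_samples == kept * int(2.0 * 250.0)
        assert report.fraction_rejected == pytest.approx(n_dropped / n_epochs_in)

    def test_annotations_cover_output(self, chain_result):
        _, out, _ = chain_result
        total = sum(a.duration for a in out.annotations)
        assert total == pytest.approx(out.duration)
        assert all(a.condition == "REST" for a in out.annotations)
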