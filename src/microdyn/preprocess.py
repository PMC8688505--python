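"""Rule-based EEG cleaning chain.

The chain mirrors standard toolbox practice for multichannel scalp EEG:
band-pass FIR filter (1-40 Hz), global bad-channel detection (flat /
low neighbor correlation / outlying amplitude), segmentation into 2-s
epochs, per-epoch local-channel QC on four statistics (variance, median
gradient, amplitude range, deviation from mean amplitude) with |Z| > 3
flagging and spherical-spline repair, segment rejection (±100 uV and
probability criteria), spherical-spline interpolation of the isolated
global bad channels, average re-referencing, and downsampling to 250 Hz.

ICA-based artifact removal is exposed only as a pass-through hook
(``ica_hook``); this package does not implement component classification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.ndimage import maximum_filter1d, minimum_filter1d
from scipy.signal import fftconvolve, firwin, resample_poly
from scipy.special import eval_legendre

from .containers import EEGRecording

__all__ = [
    "PreprocessConfig",
    "QCReport",
    "EpochedData",
    "bandpass_fir",
    "detect_bad_channels",
    "epoch",
    "faster_local_qc",
    "reject_segments",
    "spherical_spline_interpolate",
    "average_reference",
    "downsample",
    "run_preprocess",
]


@dataclass
class PreprocessConfig:
    """Thresholds of the cleaning chain (toolbox-convention defaults)."""

    filter_lo: float = 1.0
    filter_hi: float = 40.0
    transition_bw_hz: float = 1.0
    epoch_s: float = 2.0
    flat_seconds: float = 5.0
    flat_ptp_uv: float = 0.5
    neighbor_corr: float = 0.8
    n_neighbors: int = 4
    amp_sd: float = 3.0
    faster_z: float = 3.0
    reject_amp_uv: float = 100.0
    prob_sd: float = 3.0
    fs_out: float = 250.0
    ica_hook: Callable | None = None


@dataclass
class QCReport:
    """Provenance of every cleaning decision.

    Each entry names exactly one triggering criterion so dropped epochs and
    repaired channels are fully accounted for.
    """

    bad_global_channels: list[tuple[str, str]] = field(default_factory=list)
    bad_segments: list[tuple[int, str]] = field(default_factory=list)
    interpolated_local: list[tuple[int, str]] = field(default_factory=list)
    fraction_rejected: float = 0.0

    def merge(self, other: "QCReport") -> "QCReport":
        return QCReport(
            bad_global_channels=self.bad_global_channels + other.bad_global_channels,
            bad_segments=self.bad_segments + other.bad_segments,
            interpolated_local=self.interpolated_local + other.interpolated_local,
            fraction_rejected=max(self.fraction_rejected, other.fraction_rejected),
        )


@dataclass
class EpochedData:
    """Non-overlapping fixed-length epochs with per-epoch condition tags."""

    data: np.ndarray  # (n_epochs, n_channels, n_per_epoch)
    fs: float
    channel_labels: list[str]
    positions: np.ndarray
    conditions: list[str]
    runs: list[str]

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]


def bandpass_fir(
    rec: EEGRecording, lo: float, hi: float, transition_bw_hz: float = 1.0
) -> EEGRecording:
    """One-pass zero-phase Hamming windowed-sinc band-pass filter.

    The symmetric FIR kernel is applied once by convolution with
    reflection padding; its linear phase delay is compensated exactly, so
    the net filter is zero-phase.  Kernel length follows the Hamming-window
    rule of thumb (3.3 / transition bandwidth).
    """
    if not 0 < lo < hi < rec.fs / 2:
        raise ValueError("need 0 < lo < hi < Nyquist")
    numtaps = int(np.ceil(3.3 * rec.fs / transition_bw_hz))
    numtaps += 1 - numtaps % 2  # odd => integer group delay
    if rec.n_samples < numtaps:
        raise ValueError(
            f"record ({rec.n_samples} samples) shorter than filter ({numtaps} taps)"
        )
    h = firwin(numtaps, [lo, hi], pass_zero=False, window="hamming", fs=rec.fs)
    pad = numtaps // 2
    padded = np.pad(rec.data, ((0, 0), (pad, pad)), mode="reflect")
    out = fftconvolve(padded, h[None, :], mode="same", axes=1)[:, pad:-pad]
    return rec.copy_with(data=out)


def detect_bad_channels(rec: EEGRecording, cfg: PreprocessConfig | None = None) -> QCReport:
    """Flag globally bad channels by three criteria.

    * **flat** — some window longer than ``flat_seconds`` has peak-to-peak
      amplitude below ``flat_ptp_uv``;
    * **correlation** — correlation with the average of the ``n_neighbors``
      nearest electrodes falls below ``neighbor_corr``;
    * **amplitude** — the channel RMS deviates from the mean channel RMS by
      more than ``amp_sd`` times the pooled per-sample SD.
    """
    cfg = cfg or PreprocessConfig()
    if rec.n_channels < 8:
        raise ValueError("need at least 8 channels")
    report = QCReport()
    data = rec.data

    w = int(cfg.flat_seconds * rec.fs) + 1
    if w <= rec.n_samples:
        for i, lab in enumerate(rec.channel_labels):
            mx = maximum_filter1d(data[i], size=w, mode="nearest")
            mn = minimum_filter1d(data[i], size=w, mode="nearest")
            half = w // 2
            ptp = (mx - mn)[half : rec.n_samples - half]
            if ptp.size and ptp.min() < cfg.flat_ptp_uv:
                report.bad_global_channels.append((lab, "flat"))

    cosang = np.clip(rec.positions @ rec.positions.T, -1, 1)
    dist = np.arccos(cosang)
    np.fill_diagonal(dist, np.inf)
    flagged = {lab for lab, _ in report.bad_global_channels}
    for i, lab in enumerate(rec.channel_labels):
        nbrs = np.argsort(dist[i])[: cfg.n_neighbors]
        ref = data[nbrs].mean(axis=0)
        sd_i, sd_r = data[i].std(), ref.std()
        if sd_i == 0 or sd_r == 0:
            continue
        corr = np.corrcoef(data[i], ref)[0, 1]
        if corr < cfg.neighbor_corr and lab not in flagged:
            report.bad_global_channels.append((lab, "correlation"))
            flagged.add(lab)

    rms = np.sqrt((data**2).mean(axis=1))
    pooled_sd = data.std()
    if pooled_sd > 0:
        dev = np.abs(rms - rms.mean())
        for i, lab in enumerate(rec.channel_labels):
            if dev[i] > cfg.amp_sd * pooled_sd and lab not in flagged:
                report.bad_global_channels.append((lab, "amplitude"))
                flagged.add(lab)
    return report


def epoch(rec: EEGRecording, length_s: float) -> EpochedData:
    """Cut the record into consecutive non-overlapping epochs.

    The trailing remainder shorter than one epoch is dropped.  Each epoch
    inherits the condition/run of the annotation covering its midpoint
    (empty tags when none does).
    """
    n_per = length_s * rec.fs
    if abs(n_per - round(n_per)) > 1e-9:
        raise ValueError("length_s * fs must be integral")
    n_per = int(round(n_per))
    n_ep = rec.n_samples // n_per
    if n_ep == 0:
        raise ValueError("record shorter than one epoch")
    data = rec.data[:, : n_ep * n_per].reshape(rec.n_channels, n_ep, n_per)
    data = np.transpose(data, (1, 0, 2)).copy()
    conditions, runs = [], []
    for e in range(n_ep):
        mid = (e + 0.5) * length_s
        cond, run = "", ""
        for ann in rec.annotations:
            if ann.onset <= mid < ann.onset + ann.duration:
                cond, run = ann.condition, ann.run
                break
        conditions.append(cond)
        runs.append(run)
    return EpochedData(
        data=data,
        fs=rec.fs,
        channel_labels=list(rec.channel_labels),
        positions=rec.positions.copy(),
        conditions=conditions,
        runs=runs,
    )


def _faster_stats(epochs: np.ndarray) -> np.ndarray:
    """The four per-(epoch, channel) statistics, shape (4, n_ep, n_ch)."""
    var = epochs.var(axis=2)
    med_grad = np.median(np.abs(np.diff(epochs, axis=2)), axis=2)
    amp_range = epochs.max(axis=2) - epochs.min(axis=2)
    ch_mean = epochs.mean(axis=(0, 2))  # per-channel grand mean
    dev = np.abs(epochs.mean(axis=2) - ch_mean[None, :])
    return np.stack([var, med_grad, amp_range, dev])


def faster_local_qc(epochs: EpochedData, cfg: PreprocessConfig | None = None) -> QCReport:
    """Local-channel QC: four statistics Z-scored across channels per epoch.

    A channel is flagged in an epoch when any of the four |Z| exceeds the
    threshold; flagged channels are repaired by spherical-spline
    interpolation downstream, never dropped.  A zero-variance statistic
    vector (all channels identical) skips that criterion with a warning.
    """
    cfg = cfg or PreprocessConfig()
    if epochs.n_epochs < 3:
        raise ValueError("need at least 3 epochs for Z-scores")
    stats = _faster_stats(epochs.data)  # (4, n_ep, n_ch)
    names = ["variance", "median_gradient", "amplitude_range", "mean_deviation"]
    report = QCReport()
    flagged: set[tuple[int, str]] = set()
    for s, name in enumerate(names):
        mu = stats[s].mean(axis=1, keepdims=True)
        sd = stats[s].std(axis=1, keepdims=True)
        if np.any(sd == 0):
            warnings.warn(f"FASTER criterion '{name}': zero spread, skipped", stacklevel=2)
            continue
        z = (stats[s] - mu) / sd
        for e, c in zip(*np.nonzero(np.abs(z) > cfg.faster_z)):
            key = (int(e), epochs.channel_labels[c])
            if key not in flagged:
                flagged.add(key)
                report.interpolated_local.append(key)
    return report


def reject_segments(epochs: EpochedData, cfg: PreprocessConfig | None = None) -> QCReport:
    """Epoch rejection by amplitude and probability criteria.

    An epoch is dropped when any channel exceeds ±``reject_amp_uv``, when
    any channel's mean Gaussian log-likelihood (single-electrode
    probability, fitted per channel across epochs) is more than ``prob_sd``
    SDs from its across-epoch mean, or when the epoch's joint
    log-likelihood over all channels (group probability) is.
    """
    cfg = cfg or PreprocessConfig()
    data = epochs.data
    report = QCReport()
    dropped: set[int] = set()

    over = np.abs(data).max(axis=(1, 2)) > cfg.reject_amp_uv
    for e in np.flatnonzero(over):
        dropped.add(int(e))
        report.bad_segments.append((int(e), "amplitude"))

    # Gaussian log-likelihood per (epoch, channel), channel params pooled
    mu = data.mean(axis=(0, 2))
    sd = data.std(axis=(0, 2))
    sd[sd == 0] = 1.0
    zsq = ((data - mu[None, :, None]) / sd[None, :, None]) ** 2
    ll = -0.5 * zsq.mean(axis=2) - np.log(sd)[None, :]  # (n_ep, n_ch)
    z_single = (ll - ll.mean(axis=0)) / np.where(ll.std(axis=0) == 0, 1, ll.std(axis=0))
    for e in np.flatnonzero((np.abs(z_single) > cfg.prob_sd).any(axis=1)):
        if int(e) not in dropped:
            dropped.add(int(e))
            report.bad_segments.append((int(e), "single_electrode_probability"))

    ll_ep = ll.mean(axis=1)
    sd_ep = ll_ep.std()
    if sd_ep > 0:
        z_group = (ll_ep - ll_ep.mean()) / sd_ep
        for e in np.flatnonzero(np.abs(z_group) > cfg.prob_sd):
            if int(e) not in dropped:
                dropped.add(int(e))
                report.bad_segments.append((int(e), "group_probability"))

    report.fraction_rejected = len(dropped) / epochs.n_epochs
    if len(dropped) == epochs.n_epochs:
        raise RuntimeError("segment rejection dropped every epoch")
    return report


def _spline_g(cosang: np.ndarray, order: int = 4, n_terms: int = 50) -> np.ndarray:
    """Legendre-series kernel of spherical-spline interpolation (order 4)."""
    g = np.zeros_like(cosang, dtype=float)
    for n in range(1, n_terms + 1):
        g += (2 * n + 1) / (n**order * (n + 1) ** order) * eval_legendre(n, cosang)
    return g / (4 * np.pi)


def spherical_spline_matrix(
    good_pos: np.ndarray, bad_pos: np.ndarray, reg: float = 1e-5
) -> np.ndarray:
    """Interpolation operator mapping good-channel data to bad positions."""
    n_good = good_pos.shape[0]
    g_gg = _spline_g(np.clip(good_pos @ good_pos.T, -1, 1))
    g_bg = _spline_g(np.clip(bad_pos @ good_pos.T, -1, 1))
    a = np.zeros((n_good + 1, n_good + 1))
    a[:n_good, :n_good] = g_gg + reg * np.eye(n_good)
    a[:n_good, n_good] = 1.0
    a[n_good, :n_good] = 1.0
    inv = np.linalg.inv(a)
    # v_bad = [G_bg, 1] @ inv @ [v_good; 0]
    ext = np.column_stack([g_bg, np.ones(bad_pos.shape[0])])
    return ext @ inv[:, :n_good]


def spherical_spline_interpolate(rec: EEGRecording, bad: list[str]) -> EEGRecording:
    """Replace bad channels by order-4 spherical-spline estimates.

    Good channels are untouched; the spline reproduces constant fields
    exactly (the constraint term carries the mean potential).
    """
    if not bad:
        return rec.copy_with()
    bad_idx = [rec.channel_labels.index(b) for b in bad]
    good_idx = [i for i in range(rec.n_channels) if i not in bad_idx]
    if len(good_idx) < 4:
        raise ValueError("need at least 4 good channels")
    if len(bad_idx) > len(good_idx):
        raise ValueError("more bad than good channels")
    op = spherical_spline_matrix(rec.positions[good_idx], rec.positions[bad_idx])
    out = rec.data.copy()
    out[bad_idx] = op @ rec.data[good_idx]
    return rec.copy_with(data=out)


def average_reference(rec: EEGRecording) -> EEGRecording:
    """Subtract the per-sample channel mean (idempotent)."""
    out = rec.data - rec.data.mean(axis=0, keepdims=True)
    return rec.copy_with(data=out, reference="average")


def downsample(rec: EEGRecording, fs_new: float) -> EEGRecording:
    """Anti-aliased polyphase resampling to a lower rate."""
    if fs_new >= rec.fs:
        raise ValueError("fs_new must be below the current rate")
    from fractions import Fraction

    frac = Fraction(fs_new / rec.fs).limit_denominator(1000)
    out = resample_poly(rec.data, frac.numerator, frac.denominator, axis=1)
    return rec.copy_with(data=out, fs=fs_new)


def run_preprocess(
    rec: EEGRecording, cfg: PreprocessConfig | None = None
) -> tuple[EEGRecording, QCReport]:
    """Execute the full cleaning chain on one recording.

    Order: band-pass filter -> global bad-channel detection (channels
    isolated) -> optional ICA hook -> 2-s epoching -> local-channel QC with
    spline repair -> segment rejection -> spline interpolation of the
    isolated global channels -> average reference -> downsampling.
    Surviving epochs are concatenated back into a continuous record whose
    annotations reflect the per-epoch condition tags.
    """
    from .containers import Annotation

    cfg = cfg or PreprocessConfig()
    rec = bandpass_fir(rec, cfg.filter_lo, cfg.filter_hi, cfg.transition_bw_hz)
    report = detect_bad_channels(rec, cfg)
    if cfg.ica_hook is not None:
        rec = cfg.ica_hook(rec)
    bad_global = [lab for lab, _ in report.bad_global_channels]
    good_labels = [l for l in rec.channel_labels if l not in bad_global]
    good_idx = [rec.channel_labels.index(l) for l in good_labels]

    epochs = epoch(rec, cfg.epoch_s)
    work = EpochedData(
        data=epochs.data[:, good_idx, :],
        fs=epochs.fs,
        channel_labels=good_labels,
        positions=epochs.positions[good_idx],
        conditions=epochs.conditions,
        runs=epochs.runs,
    )
    local = faster_local_qc(work, cfg)
    report = report.merge(local)
    by_epoch: dict[int, list[str]] = {}
    for e, lab in local.interpolated_local:
        by_epoch.setdefault(e, []).append(lab)
    for e, labs in by_epoch.items():
        tmp = EEGRecording(
            data=work.data[e],
            fs=work.fs,
            channel_labels=work.channel_labels,
            positions=work.positions,
        )
        work.data[e] = spherical_spline_interpolate(tmp, labs).data

    seg = reject_segments(work, cfg)
    report = report.merge(seg)
    drop = {e for e, _ in seg.bad_segments}
    keep = [e for e in range(work.n_epochs) if e not in drop]

    n_per = work.data.shape[2]
    clean = np.concatenate([work.data[e] for e in keep], axis=1)
    anns = []
    pos = 0.0
    for e in keep:
        anns.append(
            Annotation(pos, n_per / work.fs, epochs.conditions[e], epochs.runs[e])
        )
        pos += n_per / work.fs
    out = EEGRecording(
        data=clean,
        fs=work.fs,
        channel_labels=work.channel_labels,
        positions=work.positions,
        annotations=anns,
    )
    if bad_global:
        # re-insert isolated channels and repair them from the clean ones
        full = np.zeros((rec.n_channels, out.n_samples))
        for i, lab in enumerate(out.channel_labels):
            full[rec.channel_labels.index(lab)] = out.data[i]
        out = EEGRecording(
            data=full,
            fs=out.fs,
            channel_labels=list(rec.channel_labels),
            positions=rec.positions.copy(),
            annotations=anns,
        )
        out = spherical_spline_interpolate(out, bad_global)
    out = average_reference(out)
    if cfg.fs_out < out.fs:
        out = downsample(out, cfg.fs_out)
    return out, report
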