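"""Synthetic EEG and symbolic sequences with planted ground truth.

Every downstream stage (preprocessing, band power, microstate clustering,
sequence dynamics) is exercised against data generated here, where the true
template maps, label sequence, dwell times, entropy rate and Hurst exponent
are known by construction.

The EEG generator plants quasi-stable topographic microstates: at sample t

    signal(t) = a(t) * Gamma_{label(t)} + noise(t)

where the label sequence is semi-Markov (geometric dwell times by default),
``a(t)`` is an alpha-band sinusoidal carrier with random phase, and the
noise is spatially smoothed white noise scaled to a requested RMS
signal-to-noise ratio.  Binary sequences with a prescribed Hurst exponent
come from sign-thresholding fractional Gaussian noise generated by exact
circulant embedding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import Annotation, EEGRecording, LabelSequence
from .microstates import MicrostateModel, spatial_correlation
from .montage import Montage

__all__ = [
    "SynthConfig",
    "make_template_maps",
    "simulate_label_sequence",
    "simulate_eeg",
    "simulate_markov_sequence",
    "simulate_hurst_sequence",
    "fractional_gaussian_noise",
    "simulate_gated_label_sequence",
]


def _uniform_offdiag(k: int) -> np.ndarray:
    if k == 1:
        return np.ones((1, 1))
    p = np.full((k, k), 1.0 / (k - 1))
    np.fill_diagonal(p, 0.0)
    return p


@dataclass
class SynthConfig:
    """Parameters of the synthetic EEG generator.

    Attributes
    ----------
    n_channels : int
    fs : float
        Sampling rate, Hz; must exceed twice the carrier frequency.
    k_true : int
        Number of planted microstate classes.
    mean_duration_ms : float
        Mean dwell time of a class before a jump; dwell times are geometric
        (memoryless) unless ``fixed_duration`` is set.
    transition_matrix : ndarray (k_true x k_true), row-stochastic
        Jump distribution at dwell ends.  Diagonal mass is allowed and is
        re-normalized away (a self-jump would merely extend the run).
        Default: uniform over the other classes.
    carrier_freq_hz : float
        Oscillatory carrier frequency (default 10 Hz, alpha band).
    snr : float
        RMS(signal)/RMS(noise), linear amplitude ratio; ``inf`` = noise-free.
    amplitude_uv : float
        Peak GFP of the noise-free signal in microvolts.
    seed : int
    fixed_duration : bool
        Use the exact configured run length instead of geometric dwells.
    """

    n_channels: int = 63
    fs: float = 500.0
    k_true: int = 7
    mean_duration_ms: float = 50.0
    transition_matrix: np.ndarray | None = None
    carrier_freq_hz: float = 10.0
    snr: float = 1.0
    amplitude_uv: float = 15.0
    seed: int = 0
    fixed_duration: bool = False

    def __post_init__(self) -> None:
        if self.mean_duration_ms <= 0:
            raise ValueError("mean_duration_ms must be positive")
        if self.fs <= 2 * self.carrier_freq_hz:
            raise ValueError("fs must exceed twice the carrier frequency")
        if self.snr <= 0:
            raise ValueError("snr must be positive (use np.inf for noise-free)")
        if self.transition_matrix is None:
            self.transition_matrix = _uniform_offdiag(self.k_true)
        p = np.asarray(self.transition_matrix, dtype=float)
        if p.shape != (self.k_true, self.k_true):
            raise ValueError("transition_matrix must be k_true x k_true")
        if np.any(p < 0) or not np.allclose(p.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("transition_matrix rows must be non-negative and sum to 1")
        self.transition_matrix = p


def _real_spherical_harmonics(positions: np.ndarray, l_max: int = 3) -> np.ndarray:
    """Real spherical-harmonic basis (degrees 1..l_max) at unit-sphere points."""
    from scipy.special import sph_harm_y

    x, y, z = positions.T
    theta = np.arccos(np.clip(z, -1, 1))  # polar
    phi = np.arctan2(y, x)  # azimuth
    cols = []
    for l in range(1, l_max + 1):
        for m in range(-l, l + 1):
            ylm = sph_harm_y(l, abs(m), theta, phi)
            if m < 0:
                col = np.sqrt(2) * (-1) ** m * ylm.imag
            elif m == 0:
                col = ylm.real
            else:
                col = np.sqrt(2) * (-1) ** m * ylm.real
            # weight low degrees more: smooth, dipole-like fields
            cols.append(col / l)
    return np.column_stack(cols)


def make_template_maps(montage: Montage, k: int, seed: int) -> MicrostateModel:
    """Random smooth template topographies with bounded mutual correlation.

    Maps are random mixtures of low-degree (<= 3) real spherical harmonics
    evaluated at the electrode positions, mean-centred across channels and
    unit-normalized.  Candidates are rejection-sampled until every pairwise
    absolute spatial correlation is <= 0.7.

    Raises
    ------
    RuntimeError
        After 1000 rejected candidates (montage too small for k).
    """
    if not 2 <= k <= montage.n_channels // 2:
        raise ValueError(f"need 2 <= k <= n_channels/2, got k={k}")
    rng = np.random.default_rng(seed)
    basis = _real_spherical_harmonics(montage.positions)
    accepted: list[np.ndarray] = []
    attempts = 0
    while len(accepted) < k:
        attempts += 1
        if attempts > 1000:
            raise RuntimeError(f"could not place {k} maps with |corr| <= 0.7 "
                               f"on a {montage.n_channels}-channel montage")
        coeffs = rng.standard_normal(basis.shape[1])
        m = basis @ coeffs
        m = m - m.mean()
        norm = np.linalg.norm(m)
        if norm == 0:
            continue
        m = m / norm
        if accepted:
            corr = spatial_correlation(np.stack(accepted), m[None, :])
            if np.max(np.abs(corr)) > 0.7:
                continue
        accepted.append(m)
    return MicrostateModel(
        maps=np.stack(accepted), channel_labels=list(montage.channel_labels), seed=seed
    )


def simulate_label_sequence(cfg: SynthConfig, n_samples: int) -> LabelSequence:
    """Semi-Markov label sequence with the configured dwell-time statistics.

    Dwell times are geometric with mean ``fs * mean_duration_ms / 1000``
    samples (support 1, 2, ...), or exactly that many samples in
    fixed-duration mode.  Jumps at dwell ends follow the transition matrix
    with diagonal mass removed and re-normalized.
    """
    k = cfg.k_true
    mean_run = cfg.fs * cfg.mean_duration_ms / 1000.0
    if mean_run < 1.0:
        raise ValueError("mean dwell shorter than one sample at this fs")
    if n_samples < 10 * mean_run:
        raise ValueError("n_samples must cover at least 10 expected runs")
    rng = np.random.default_rng(cfg.seed)
    if k == 1:
        return LabelSequence(np.zeros(n_samples, dtype=np.int64), cfg.fs, 1)

    p = cfg.transition_matrix.copy()
    np.fill_diagonal(p, 0.0)
    rowsums = p.sum(axis=1)
    if np.any(rowsums <= 0):
        raise ValueError("a transition row has no off-diagonal mass")
    p /= rowsums[:, None]
    cum = np.cumsum(p, axis=1)

    labels = np.empty(n_samples, dtype=np.int64)
    pos = 0
    state = int(rng.integers(k))
    geo_p = 1.0 / mean_run
    while pos < n_samples:
        if cfg.fixed_duration:
            run = int(round(mean_run))
        else:
            run = int(rng.geometric(geo_p))
        run = min(run, n_samples - pos)
        labels[pos : pos + run] = state
        pos += run
        state = int(np.searchsorted(cum[state], rng.random()))
    return LabelSequence(labels, cfg.fs, k)


def _spatial_smoothing_matrix(positions: np.ndarray, sigma_rad: float = 0.5) -> np.ndarray:
    cosang = np.clip(positions @ positions.T, -1.0, 1.0)
    dist = np.arccos(cosang)
    w = np.exp(-(dist**2) / (2 * sigma_rad**2))
    return w / w.sum(axis=1, keepdims=True)


def simulate_eeg(
    maps: MicrostateModel,
    labels: LabelSequence,
    cfg: SynthConfig,
    *,
    montage: Montage | None = None,
    condition: str = "",
    run: str = "run1",
) -> EEGRecording:
    """Assemble EEG from planted maps, a label sequence, carrier and noise.

    The noise-free topography at sample t is the planted map of ``label(t)``
    scaled by a random-phase sinusoidal carrier whose peak GFP equals
    ``cfg.amplitude_uv``.  Spatially smoothed white noise is added with
    RMS(signal)/RMS(noise) = ``cfg.snr``.  Output is in the original
    reference state (the signal part is average-reference-free because the
    maps are zero-mean across channels).
    """
    if maps.n_channels != cfg.n_channels:
        raise ValueError("map and config channel counts disagree")
    if labels.n_classes > maps.n_classes:
        raise ValueError("label sequence uses more classes than maps provide")
    rng = np.random.default_rng(cfg.seed + 1)
    t = np.arange(len(labels)) / labels.fs
    phase = rng.uniform(0, 2 * np.pi)
    # zero-mean unit-norm map => per-sample GFP of the signal = |a(t)|/sqrt(C)
    carrier = (
        cfg.amplitude_uv
        * np.sqrt(cfg.n_channels)
        * np.sin(2 * np.pi * cfg.carrier_freq_hz * t + phase)
    )
    signal = maps.maps[labels.labels].T * carrier  # (C, T)

    if np.isinf(cfg.snr):
        data = signal
    else:
        if montage is not None:
            smooth = _spatial_smoothing_matrix(montage.positions)
        else:
            smooth = np.eye(cfg.n_channels)
        noise = smooth @ rng.standard_normal(signal.shape)
        rms_sig = np.sqrt((signal**2).mean())
        rms_noise = np.sqrt((noise**2).mean())
        noise *= rms_sig / (cfg.snr * rms_noise)
        data = signal + noise

    if montage is not None:
        ch_labels = list(montage.channel_labels)
        positions = montage.positions.copy()
    else:
        ch_labels = list(maps.channel_labels)
        positions = np.tile([0.0, 0.0, 1.0], (cfg.n_channels, 1))
    ann = [Annotation(0.0, len(labels) / labels.fs, condition, run)] if condition else []
    return EEGRecording(
        data=data,
        fs=labels.fs,
        channel_labels=ch_labels,
        positions=positions,
        reference="original",
        annotations=ann,
    )


def _stationary_distribution(p: np.ndarray) -> np.ndarray:
    k = p.shape[0]
    if np.allclose(p, np.eye(k)):
        # every distribution is stationary; start uniformly (constant chains)
        return np.full(k, 1.0 / k)
    vals, vecs = np.linalg.eig(p.T)
    close = np.isclose(vals, 1.0, atol=1e-9)
    if close.sum() != 1:
        raise ValueError("chain has no unique stationary distribution (reducible?)")
    pi = np.real(vecs[:, np.argmax(close)])
    pi = np.abs(pi)
    return pi / pi.sum()


def simulate_markov_sequence(p: np.ndarray, n: int, seed: int, fs: float = 250.0) -> LabelSequence:
    """First-order Markov chain started from its stationary distribution."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 2 or p.shape[0] != p.shape[1]:
        raise ValueError("P must be square")
    if np.any(p < 0) or not np.allclose(p.sum(axis=1), 1.0, atol=1e-10):
        raise ValueError("P rows must sum to 1")
    k = p.shape[0]
    pi = _stationary_distribution(p)
    rng = np.random.default_rng(seed)
    cum = np.cumsum(p, axis=1)
    u = rng.random(n)
    labels = np.empty(n, dtype=np.int64)
    state = int(np.searchsorted(np.cumsum(pi), rng.random()))
    for i in range(n):
        labels[i] = state
        state = int(np.searchsorted(cum[state], u[i]))
    return LabelSequence(labels, fs, k)


def fractional_gaussian_noise(hurst: float, n: int, seed: int) -> np.ndarray:
    """Exact fractional Gaussian noise by Davies-Harte circulant embedding.

    Returns a length-n standard-variance fGn sample with Hurst exponent
    ``hurst``.  Raises if the circulant eigenvalues turn negative (embedding
    not valid for this n/H combination).
    """
    if not 0 < hurst < 1:
        raise ValueError("hurst must be in (0, 1)")
    m = 1 << max(1, int(np.ceil(np.log2(n))))
    k = np.arange(m + 1, dtype=float)
    gamma = 0.5 * (
        np.abs(k + 1) ** (2 * hurst)
        - 2 * np.abs(k) ** (2 * hurst)
        + np.abs(k - 1) ** (2 * hurst)
    )
    row = np.concatenate([gamma[: m + 1], gamma[m - 1 : 0 : -1]])  # length 2m
    lam = np.fft.fft(row).real
    if lam.min() < -1e-8:
        raise ValueError(f"circulant embedding failed for n={n}, H={hurst}")
    lam = np.clip(lam, 0.0, None)
    rng = np.random.default_rng(seed)
    two_m = 2 * m
    v = np.empty(two_m, dtype=complex)
    v[0] = rng.standard_normal() * np.sqrt(two_m)
    v[m] = rng.standard_normal() * np.sqrt(two_m)
    re = rng.standard_normal(m - 1)
    im = rng.standard_normal(m - 1)
    v[1:m] = (re + 1j * im) * np.sqrt(m)
    v[m + 1 :] = np.conj(v[1:m][::-1])
    x = np.fft.ifft(np.sqrt(lam) * v)
    return x.real[:n]


def simulate_hurst_sequence(hurst: float, n: int, seed: int, fs: float = 250.0) -> LabelSequence:
    """Binary sequence with prescribed Hurst exponent.

    Sign-thresholded fractional Gaussian noise: the {0,1} label sequence
    maps to {-1,+1} with the same long-range correlation structure as the
    underlying fGn (the arcsine law preserves the power-law tail of the
    autocorrelation, hence the Hurst exponent).
    """
    fgn = fractional_gaussian_noise(hurst, n, seed)
    return LabelSequence((fgn > 0).astype(np.int64), fs, 2)


def simulate_gated_label_sequence(
    cfg: SynthConfig,
    n_samples: int,
    *,
    gate_hurst: float | None = None,
    gate_hold_samples: int = 25,
    seed_offset: int = 0,
) -> LabelSequence:
    """Label sequence whose class-group membership carries long-range memory.

    Two independent semi-Markov sequences run over the first
    ``ceil(k/2)`` and remaining classes; a binary gate selects which one is
    visible at each sample.  The gate is the sign of fractional Gaussian
    noise with exponent ``gate_hurst``, held constant over blocks of
    ``gate_hold_samples`` samples so dwell structure survives.  With
    ``gate_hurst`` around 0.5 the sequence has no long-range correlation;
    larger values plant a correspondingly larger mean Hurst exponent over
    the class bipartitions.  ``gate_hurst=None`` returns the plain
    semi-Markov sequence.
    """
    if gate_hurst is None:
        return simulate_label_sequence(cfg, n_samples)
    k = cfg.k_true
    if k < 2:
        raise ValueError("gating needs at least 2 classes")
    ka = (k + 1) // 2
    kb = k - ka
    import dataclasses

    cfg_a = dataclasses.replace(cfg, k_true=ka, transition_matrix=None, seed=cfg.seed + seed_offset)
    cfg_b = dataclasses.replace(
        cfg, k_true=max(kb, 1), transition_matrix=None, seed=cfg.seed + seed_offset + 1
    )
    seq_a = simulate_label_sequence(cfg_a, n_samples)
    if kb >= 2:
        seq_b = simulate_label_sequence(cfg_b, n_samples)
        labels_b = seq_b.labels + ka
    else:
        labels_b = np.full(n_samples, ka, dtype=np.int64)
    n_blocks = int(np.ceil(n_samples / gate_hold_samples))
    fgn = fractional_gaussian_noise(gate_hurst, n_blocks, cfg.seed + seed_offset + 2)
    gate = np.repeat(fgn > 0, gate_hold_samples)[:n_samples]
    labels = np.where(gate, seq_a.labels, labels_b)
    return LabelSequence(labels, cfg.fs, k)
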