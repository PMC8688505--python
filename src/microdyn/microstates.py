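"""EEG microstate model estimation and back-fitting.

A microstate model is a set of K unit-norm template topographies.  Templates
are estimated from the EEG topographies at peaks of the global field power
(GFP) with a polarity-invariant modified k-means: each sample is assigned to
the template maximizing the squared spatial projection, and each template is
updated as the dominant eigenvector of its assigned samples.  The cost

    F = (1/(N_T (N_S - 1))) * sum_t || V_t - a_t Gamma_{L(t)} ||^2

(with a_t the projection of sample V_t onto its template) never increases
across iterations.  Model selection uses the cross-validation criterion

    CV = sigma2 * ((N_S - 1) / (N_S - 1 - N_K))^2

where sigma2 is the mean residual variance.  Back-fitting assigns every EEG
sample to the template with the highest absolute spatial correlation, with
no temporal smoothing, producing the label sequences consumed by the
sequence-dynamics statistics.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .containers import EEGRecording, LabelSequence

__all__ = [
    "GFPSeries",
    "MicrostateModel",
    "MicrostateParams",
    "gfp",
    "gfp_peaks",
    "modified_kmeans",
    "select_optimal_k",
    "align_maps_group",
    "backfit",
    "gev",
    "microstate_parameters",
    "spatial_correlation",
]


@dataclass
class GFPSeries:
    """Global field power: per-sample SD of potentials across electrodes."""

    values: np.ndarray
    fs: float
    peak_indices: np.ndarray | None = None


@dataclass
class MicrostateModel:
    """K unit-norm template topographies with fit diagnostics.

    ``maps`` has shape (K, n_channels); each row is zero-mean (average
    reference) and unit-norm.  The model is identical under a sign flip of
    any map (polarity invariance).
    """

    maps: np.ndarray
    channel_labels: list[str]
    cost_f: float = np.nan
    cv: float = np.nan
    gev_: float = np.nan
    seed: int | None = None
    label_names: list[str] | None = None
    n_iter: int | None = None
    cost_history: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=float)
        if self.maps.ndim != 2:
            raise ValueError("maps must be (K, n_channels)")
        norms = np.linalg.norm(self.maps, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("each map must be unit-norm")

    @property
    def n_classes(self) -> int:
        return self.maps.shape[0]

    @property
    def n_channels(self) -> int:
        return self.maps.shape[1]


@dataclass
class MicrostateParams:
    """Per-class duration / occurrence / coverage of a label sequence."""

    duration_ms: np.ndarray  # NaN where class absent
    occurrence_hz: np.ndarray
    coverage: np.ndarray
    n_classes: int


def gfp(rec: EEGRecording) -> GFPSeries:
    """Global field power: population SD across channels per sample.

    Invariant to adding a constant to all channels at a sample.
    """
    if rec.n_channels < 2:
        raise ValueError("GFP needs at least 2 channels")
    values = rec.data.std(axis=0, ddof=0)
    return GFPSeries(values=values, fs=rec.fs)


def gfp_peaks(series: GFPSeries, min_separation_ms: float = 0.0) -> np.ndarray:
    """Indices of strict local maxima of the GFP curve.

    A plateau of equal values yields its first sample only.  With a positive
    ``min_separation_ms``, peaks closer than that to a previously accepted
    (higher-first, greedy in time) peak are dropped.
    """
    v = series.values
    if v.size < 3:
        raise ValueError("series too short for peak detection")
    # strict rise then fall; plateaus resolved to their first sample
    rising = np.empty(v.size, dtype=bool)
    rising[0] = False
    rising[1:] = v[1:] > v[:-1]
    falling = np.empty(v.size, dtype=bool)
    falling[-1] = False
    # value strictly greater than the next *different* value
    nxt = v.copy()
    for i in range(v.size - 2, -1, -1):
        if v[i] == v[i + 1]:
            nxt[i] = nxt[i + 1]
        else:
            nxt[i] = v[i + 1]
    falling[:-1] = v[:-1] > nxt[:-1]
    peaks = np.flatnonzero(rising & falling)
    if min_separation_ms > 0 and peaks.size:
        min_gap = min_separation_ms * series.fs / 1000.0
        kept = [peaks[0]]
        for p in peaks[1:]:
            if p - kept[-1] >= min_gap:
                kept.append(p)
        peaks = np.asarray(kept)
    series.peak_indices = peaks
    return peaks


def spatial_correlation(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson correlation across channels between topography sets.

    Parameters are (..., n_channels) arrays; topographies are mean-centred
    across channels before the normalized inner product, so the result is
    the standard spatial correlation of average-referenced maps.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ac = a - a.mean(axis=-1, keepdims=True)
    bc = b - b.mean(axis=-1, keepdims=True)
    na = np.linalg.norm(ac, axis=-1, keepdims=True)
    nb = np.linalg.norm(bc, axis=-1, keepdims=True)
    na[na == 0] = 1.0
    nb[nb == 0] = 1.0
    return (ac / na) @ (bc / nb).swapaxes(-1, -2) if b.ndim > 1 else (ac / na) @ (bc / nb[..., 0])


def _normalize_maps(maps: np.ndarray) -> np.ndarray:
    maps = maps - maps.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(maps, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return maps / norms


def _cost_and_labels(x: np.ndarray, maps: np.ndarray) -> tuple[float, np.ndarray]:
    """Modified k-means cost F and polarity-ignored assignments."""
    proj = x @ maps.T  # (T, K)
    labels = np.argmax(proj**2, axis=1)
    best = proj[np.arange(x.shape[0]), labels]
    t, c = x.shape
    resid = (x**2).sum() - (best**2).sum()
    return resid / (t * (c - 1)), labels


def _update_maps(x: np.ndarray, labels: np.ndarray, maps: np.ndarray, rng) -> np.ndarray:
    k = maps.shape[0]
    new = maps.copy()
    proj = x @ maps.T
    for j in range(k):
        sel = labels == j
        if not sel.any():
            # reseed an empty cluster from the worst-fit sample
            best = proj[np.arange(x.shape[0]), np.argmax(proj**2, axis=1)]
            fit = best**2 / np.maximum((x**2).sum(axis=1), 1e-300)
            worst = int(np.argmin(fit))
            new[j] = x[worst]
            continue
        xs = x[sel]
        # dominant eigenvector of sum_t x_t x_t' via the channel covariance
        s = xs.T @ xs
        vals, vecs = np.linalg.eigh(s)
        new[j] = vecs[:, -1]
    return _normalize_maps(new)


def modified_kmeans(
    peak_maps: np.ndarray,
    k: int,
    *,
    n_restarts: int = 20,
    seed: int | None = None,
    max_iter: int = 1000,
    tol: float = 1e-6,
    channel_labels: list[str] | None = None,
) -> MicrostateModel:
    """Polarity-invariant modified k-means over topographies.

    Parameters
    ----------
    peak_maps : ndarray, shape (n_samples, n_channels)
        Average-referenced topographies (usually at GFP peaks).
    k : int
        Number of template classes.
    n_restarts : int
        Independent restarts; the model with minimum cost F is retained.
    seed : int, optional
        Seed for the restart initializations.

    Notes
    -----
    Each restart initializes the templates from k distinct random samples,
    then alternates polarity-ignored assignment and dominant-eigenvector map
    updates until the relative change in F falls below ``tol``.  F never
    increases across iterations.  The CV criterion of the winning model is
    computed on the final assignment.
    """
    x = np.asarray(peak_maps, dtype=float)
    if x.ndim != 2:
        raise ValueError("peak_maps must be (n_samples, n_channels)")
    t, c = x.shape
    if not 2 <= k <= t:
        raise ValueError(f"k={k} out of range for {t} samples")
    if t < 20 * k:
        warnings.warn(f"only {t} samples for k={k}; recommend >= {20*k}", stacklevel=2)
    rng = np.random.default_rng(seed)

    best_f = np.inf
    best_maps = None
    best_labels = None
    best_iter = 0
    best_history: list[float] = []
    for _ in range(n_restarts):
        init_idx = rng.choice(t, size=k, replace=False)
        maps = _normalize_maps(x[init_idx].copy())
        f_prev = np.inf
        history: list[float] = []
        for it in range(max_iter):
            f, labels = _cost_and_labels(x, maps)
            history.append(f)
            if np.isfinite(f_prev) and f_prev - f <= tol * max(f_prev, 1e-300):
                break
            f_prev = f
            maps = _update_maps(x, labels, maps, rng)
        f, labels = _cost_and_labels(x, maps)
        history.append(f)
        if f < best_f:
            best_f, best_maps, best_labels = f, maps, labels
            best_iter, best_history = it + 1, history

    sigma2 = best_f  # mean residual variance per Eq.-(2) normalization
    if c - 1 - k > 0:
        cv = sigma2 * ((c - 1) / (c - 1 - k)) ** 2
    else:
        cv = np.nan
    model = MicrostateModel(
        maps=best_maps,
        channel_labels=channel_labels or [f"ch{i}" for i in range(c)],
        cost_f=float(best_f),
        cv=float(cv),
        seed=seed,
        n_iter=best_iter,
    )
    model.cost_history = np.asarray(best_history)
    model.gev_ = gev(x, model, best_labels)
    return model


def select_optimal_k(
    peak_maps: np.ndarray,
    k_range=range(2, 11),
    *,
    n_restarts: int = 100,
    seed: int | None = None,
    channel_labels: list[str] | None = None,
) -> tuple[int, dict[int, MicrostateModel]]:
    """Fit all cluster counts in ``k_range``; return the CV-minimizing K.

    K values for which the CV penalty is undefined (``N_S - 1 - K <= 0``)
    are skipped with a warning.  All fitted models are retained.
    """
    x = np.asarray(peak_maps, dtype=float)
    c = x.shape[1]
    models: dict[int, MicrostateModel] = {}
    rng = np.random.default_rng(seed)
    for k in k_range:
        if c - 1 - k <= 0:
            warnings.warn(f"k={k} skipped: CV undefined for {c} channels", stacklevel=2)
            continue
        sub_seed = int(rng.integers(2**31 - 1))
        models[k] = modified_kmeans(
            x, k, n_restarts=n_restarts, seed=sub_seed, channel_labels=channel_labels
        )
    if not models:
        raise ValueError("no valid k in range")
    k_star = min(models, key=lambda k: models[k].cv)
    return k_star, models


def _best_permutation(corr_abs: np.ndarray, exhaustive: bool) -> np.ndarray:
    """Permutation p maximizing sum_k |corr|[p[k], k]."""
    k = corr_abs.shape[0]
    if exhaustive and k <= 7:
        best, best_score = None, -np.inf
        for perm in itertools.permutations(range(k)):
            score = corr_abs[perm, range(k)].sum()
            if score > best_score:
                best, best_score = perm, score
        return np.asarray(best)
    row, col = linear_sum_assignment(-corr_abs)
    perm = np.empty(k, dtype=int)
    perm[col] = row
    return perm


def align_maps_group(
    subject_models: list[MicrostateModel], *, max_sweeps: int = 100
) -> tuple[MicrostateModel, list[np.ndarray]]:
    """Align subject microstate maps to a common group labeling.

    Iteratively finds, per subject, the label permutation (with sign flips
    folded in by the absolute correlation) maximizing the mean |spatial
    correlation| to the evolving group-mean maps; group maps are the
    dominant eigenvectors of the aligned subject maps.  For K <= 7 the
    permutation search is exhaustive (the full K! sweep); larger K uses the
    Hungarian assignment, which optimizes the same separable objective.

    Returns the group model and the per-subject permutations
    (``perm[k]`` = index of the subject map assigned to group class k).
    """
    k = subject_models[0].n_classes
    c = subject_models[0].n_channels
    for m in subject_models:
        if m.n_classes != k or m.n_channels != c:
            raise ValueError("all models must share K and channel count")
    stack = np.stack([m.maps for m in subject_models])  # (S, K, C)
    perms = [np.arange(k) for _ in subject_models]
    group = stack[0].copy()
    for _ in range(max_sweeps):
        changed = False
        for s, model in enumerate(subject_models):
            corr = np.abs(spatial_correlation(model.maps, group))  # (K_subj, K_group)
            perm = _best_permutation(corr, exhaustive=True)
            if not np.array_equal(perm, perms[s]):
                perms[s] = perm
                changed = True
        # group maps: dominant eigenvector per class of aligned subject maps
        new_group = np.empty_like(group)
        for j in range(k):
            maps_j = np.stack([stack[s][perms[s][j]] for s in range(len(subject_models))])
            s_mat = maps_j.T @ maps_j
            vals, vecs = np.linalg.eigh(s_mat)
            new_group[j] = vecs[:, -1]
        new_group = _normalize_maps(new_group)
        if not changed and np.allclose(np.abs((new_group * group).sum(axis=1)), 1.0, atol=1e-9):
            group = new_group
            break
        group = new_group
    else:
        warnings.warn("group alignment did not converge; returning best found", stacklevel=2)
    gm = MicrostateModel(maps=group, channel_labels=subject_models[0].channel_labels)
    return gm, perms


def backfit(rec: EEGRecording, model: MicrostateModel, condition: str = "") -> LabelSequence:
    """Assign every EEG sample to the template with highest |spatial corr|.

    Polarity is ignored and no temporal smoothing or minimum-duration
    constraint is applied.  Zero-GFP samples (undefined correlation) inherit
    the previous sample's label; a leading zero-GFP sample gets class 0.
    Ties break to the lowest class index (argmax convention).
    """
    if rec.n_channels != model.n_channels:
        raise ValueError("channel count mismatch between recording and model")
    x = rec.data.T  # (T, C)
    xc = x - x.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(xc, axis=1)
    maps = _normalize_maps(model.maps)
    corr = np.abs(xc @ maps.T)  # proportional to |corr| per sample
    labels = np.argmax(corr, axis=1)
    zero = norms == 0
    if zero.any():
        labels = labels.copy()
        prev = 0
        for i in range(labels.size):
            if zero[i]:
                labels[i] = prev
            else:
                prev = labels[i]
    return LabelSequence(
        labels=labels, fs=rec.fs, n_classes=model.n_classes, condition=condition
    )


def gev(peak_maps: np.ndarray, model: MicrostateModel, labels: np.ndarray) -> float:
    """Global explained variance at GFP peaks.

    GFP^2-weighted mean of the squared spatial correlation between each peak
    topography and its assigned template, in [0, 1]; invariant to map sign
    flips.
    """
    x = np.asarray(peak_maps, dtype=float)
    labels = np.asarray(labels)
    if x.size == 0 or labels.size == 0:
        raise ValueError("gev needs non-empty peak maps and labels")
    g2 = x.var(axis=1, ddof=0)  # squared GFP per sample
    assigned = model.maps[labels]
    corr = spatial_correlation(x[:, None, :], assigned[:, None, :])[:, 0, 0]
    total = g2.sum()
    if total == 0:
        raise ValueError("zero total GFP")
    return float((g2 * corr**2).sum() / total)


def canonical_templates(positions: np.ndarray, labels=None) -> dict[str, np.ndarray]:
    """SYNTHETIC approximations of the literature's A-G template classes.

    These are parametric stand-ins (linear and Gaussian-blob fields on the
    electrode sphere oriented like the published class descriptions: A/B the
    two diagonal gradients, C anterior-posterior, D fronto-central, E
    centro-parietal, F prefrontal, G occipito-parietal).  They are NOT the
    published group templates — use them only to attach conventional names
    to fitted maps, never as fitting targets.
    """
    pos = np.asarray(positions, dtype=float)

    def linear(direction):
        v = pos @ (np.asarray(direction) / np.linalg.norm(direction))
        return v

    def blob(center, width=0.8):
        c = np.asarray(center) / np.linalg.norm(center)
        d = np.linalg.norm(pos - c, axis=1)
        return np.exp(-((d / width) ** 2))

    raw = {
        "A": linear([1.0, 1.0, 0.0]),
        "B": linear([-1.0, 1.0, 0.0]),
        "C": linear([0.0, 1.0, 0.3]),
        "D": blob([0.0, 0.45, 0.89]),
        "E": blob([0.0, -0.30, 0.95]),
        "F": blob([0.0, 0.95, 0.30]),
        "G": blob([0.0, -0.85, 0.53]),
    }
    out = {}
    for name, m in raw.items():
        m = m - m.mean()
        out[name] = m / np.linalg.norm(m)
    return out


def assign_canonical_names(model: MicrostateModel, positions: np.ndarray) -> list[str]:
    """Name fitted maps A-G by |spatial correlation| to the synthetic
    canonical templates (greedy one-to-one matching, non-authoritative)."""
    templates = canonical_templates(positions)
    names = list(templates)
    t = np.stack([templates[n] for n in names])
    corr = np.abs(spatial_correlation(model.maps, t))  # (K, 7)
    k = model.n_classes
    if k > len(names):
        raise ValueError("more maps than canonical names")
    row, col = linear_sum_assignment(-corr)
    assigned = [""] * k
    for r, c in zip(row, col):
        assigned[r] = names[c]
    model.label_names = assigned
    return assigned


def microstate_parameters(seq: LabelSequence) -> MicrostateParams:
    """Run-length statistics of a label sequence.

    duration_ms[k]  — mean run length of class k in ms (NaN if absent)
    occurrence_hz[k] — class-k runs per second
    coverage[k]     — fraction of samples labeled k (sums to 1 exactly)
    """
    labels = seq.labels
    n = labels.size
    change = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [n]])
    run_labels = labels[starts]
    run_lengths = ends - starts
    k = seq.n_classes
    duration = np.full(k, np.nan)
    occurrence = np.zeros(k)
    coverage = np.zeros(k)
    seconds = n / seq.fs
    for j in range(k):
        sel = run_labels == j
        if sel.any():
            duration[j] = run_lengths[sel].mean() * 1000.0 / seq.fs
            occurrence[j] = sel.sum() / seconds
        coverage[j] = (labels == j).sum() / n
    return MicrostateParams(
        duration_ms=duration, occurrence_hz=occurrence, coverage=coverage, n_classes=k
    )
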