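"""Electrode montages on the unit sphere.

Coordinates come from the standard 10-05/10-10 idealized head table bundled
with MNE-Python, re-centred and projected onto the unit sphere.  The default
63-channel montage mirrors a 64-channel actiCHamp cap referenced at Cz
(Cz itself excluded after average re-referencing).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["Montage", "standard_1010_montage", "ACTICAP64_LABELS"]

# 64-channel actiCAP layout (10-10 names); Cz is the recording reference.
ACTICAP64_LABELS = [
    "Fp1", "Fz", "F3", "F7", "FT9", "FC5", "FC1", "C3", "T7", "TP9",
    "CP5", "CP1", "Pz", "P3", "P7", "O1", "Oz", "O2", "P4", "P8",
    "TP10", "CP6", "CP2", "Cz", "C4", "T8", "FT10", "FC6", "FC2", "F4",
    "F8", "Fp2", "AF7", "AF3", "AFz", "F1", "F5", "FT7", "FC3", "C1",
    "C5", "TP7", "CP3", "P1", "P5", "PO7", "PO3", "POz", "PO4", "PO8",
    "P6", "P2", "CPz", "CP4", "TP8", "C6", "C2", "FC4", "FT8", "F6",
    "AF8", "AF4", "F2", "Iz",
]


@dataclass(frozen=True)
class Montage:
    """A set of named electrodes with unit-sphere positions.

    Invariants: labels unique, every position unit-norm (1e-9), >= 8 channels.
    """

    channel_labels: tuple[str, ...]
    positions: np.ndarray  # (n_channels, 3)

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "positions", pos)
        n = len(self.channel_labels)
        if n < 8:
            raise ValueError("montage needs at least 8 channels")
        if len(set(self.channel_labels)) != n:
            raise ValueError("duplicate channel labels")
        if pos.shape != (n, 3):
            raise ValueError("positions must be (n_channels, 3)")
        norms = np.linalg.norm(pos, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("positions must have unit norm")

    @property
    def n_channels(self) -> int:
        return len(self.channel_labels)

    def index(self, label: str) -> int:
        return self.channel_labels.index(label)

    def subset(self, labels) -> "Montage":
        idx = [self.index(l) for l in labels]
        return Montage(tuple(labels), self.positions[idx])

    def nearest_neighbors(self, k: int = 4) -> dict[str, list[str]]:
        """k nearest electrodes per channel by great-circle distance."""
        cosang = np.clip(self.positions @ self.positions.T, -1.0, 1.0)
        dist = np.arccos(cosang)
        out: dict[str, list[str]] = {}
        for i, lab in enumerate(self.channel_labels):
            order = np.argsort(dist[i])
            nbrs = [self.channel_labels[j] for j in order if j != i][:k]
            out[lab] = nbrs
        return out


def _mne_head_positions(labels) -> np.ndarray:
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        std = mne.channels.make_standard_montage("standard_1005")
    ch_pos = std.get_positions()["ch_pos"]
    missing = [l for l in labels if l not in ch_pos]
    if missing:
        raise KeyError(f"labels not in the standard 10-05 table: {missing}")
    return np.array([ch_pos[l] for l in labels], dtype=float)


def standard_1010_montage(labels=None, *, include_reference: bool = False) -> Montage:
    """Build a 10-10 montage with unit-sphere positions.

    Parameters
    ----------
    labels : sequence of str, optional
        Electrode names.  Default: the 64-channel actiCAP layout without the
        Cz reference (63 channels).
    include_reference : bool
        With the default label set, keep Cz as a data channel.
    """
    if labels is None:
        labels = list(ACTICAP64_LABELS)
        if not include_reference:
            labels.remove("Cz")
    pos = _mne_head_positions(labels)
    # Algebraic best-fit sphere (electrodes cover only the upper head, so the
    # centroid is a poor centre); then radial projection onto the unit sphere.
    A = np.column_stack([2.0 * pos, np.ones(len(pos))])
    b = (pos**2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    pos = pos - sol[:3]
    pos /= np.linalg.norm(pos, axis=1, keepdims=True)
    return Montage(tuple(labels), pos)
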