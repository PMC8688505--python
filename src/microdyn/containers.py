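"""Core in-memory containers shared by all analysis stages.

The two central objects are :class:`EEGRecording` (a channels x samples
potential matrix with montage and condition metadata) and
:class:`LabelSequence` (a per-sample categorical microstate sequence, the
object every temporal statistic consumes).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["Annotation", "EEGRecording", "LabelSequence"]


@dataclass(frozen=True)
class Annotation:
    """A condition-tagged span of a recording.

    Parameters
    ----------
    onset : float
        Start of the span in seconds from the beginning of the record.
    duration : float
        Length of the span in seconds.
    condition : str
        Condition tag, e.g. ``"REST"`` or ``"IG"``.
    run : str
        Run tag, e.g. ``"run1"``.
    """

    onset: float
    duration: float
    condition: str
    run: str = "run1"


@dataclass
class EEGRecording:
    """Multichannel scalp EEG segment.

    Attributes
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Potentials in microvolts.
    fs : float
        Sampling rate in Hz.
    channel_labels : list of str
        10-10 system electrode names, unique.
    positions : ndarray, shape (n_channels, 3)
        Unit-sphere sensor coordinates.
    reference : {"original", "average"}
        Current referencing state of ``data``.
    annotations : list of Annotation
        Condition/run spans; must lie within the record duration.
    """

    data: np.ndarray
    fs: float
    channel_labels: list[str]
    positions: np.ndarray
    reference: str = "original"
    annotations: list[Annotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite values")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        n_ch = self.data.shape[0]
        if len(self.channel_labels) != n_ch:
            raise ValueError("channel_labels length does not match data rows")
        if len(set(self.channel_labels)) != n_ch:
            raise ValueError("channel labels must be unique")
        if self.positions.shape != (n_ch, 3):
            raise ValueError("positions must be (n_channels, 3)")
        if self.reference not in ("original", "average"):
            raise ValueError("reference must be 'original' or 'average'")
        dur = self.duration
        for ann in self.annotations:
            if ann.onset < 0 or ann.onset + ann.duration > dur + 1e-9:
                raise ValueError(
                    f"annotation {ann} extends beyond record duration {dur:.3f} s"
                )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.data.shape[1] / self.fs

    def copy_with(self, **changes) -> "EEGRecording":
        """Return a copy with selected fields replaced (data is copied)."""
        out = replace(self, **changes)
        if "data" not in changes:
            out.data = self.data.copy()
        return out

    def crop(self, start_s: float, stop_s: float) -> "EEGRecording":
        """Extract ``[start_s, stop_s)`` as a new recording (annotations dropped)."""
        i0 = int(round(start_s * self.fs))
        i1 = int(round(stop_s * self.fs))
        if not 0 <= i0 < i1 <= self.n_samples:
            raise ValueError("crop bounds outside record")
        return EEGRecording(
            data=self.data[:, i0:i1].copy(),
            fs=self.fs,
            channel_labels=list(self.channel_labels),
            positions=self.positions.copy(),
            reference=self.reference,
            annotations=[],
        )


@dataclass
class LabelSequence:
    """Per-sample categorical class labels at a known sampling rate.

    ``labels`` are integers in ``[0, n_classes)``.  All sequence statistics
    (entropy rate, autoinformation, DFA) operate on this object.
    """

    labels: np.ndarray
    fs: float
    n_classes: int
    condition: str = ""

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 1 or self.labels.size == 0:
            raise ValueError("labels must be a non-empty 1-D array")
        if not np.issubdtype(self.labels.dtype, np.integer):
            lab = self.labels.astype(np.int64)
            if not np.array_equal(lab, self.labels):
                raise ValueError("labels must be integers")
            self.labels = lab
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.labels.min() < 0 or self.labels.max() >= self.n_classes:
            raise ValueError("labels out of range [0, n_classes)")

    def __len__(self) -> int:
        return self.labels.size

    @property
    def duration(self) -> float:
        return self.labels.size / self.fs
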