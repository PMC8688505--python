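"""Task-related band power (TRP) analysis.

Power spectral densities come from Welch's method (Hann window of 500
samples, 250-sample overlap at the 250-Hz analysis rate); band powers are
trapezoidal integrals of the PSD over the canonical bands

    delta 1-3.5 Hz, theta 4-7.5 Hz, alpha 8-13.5 Hz, beta 14-29 Hz.

Task-related power per channel is the log band-power difference between a
task condition and the first eyes-closed rest block:

    TRP_i = log10(Pow_i,task) - log10(Pow_i,rest)

so positive values mean task-related power increase (synchronization) and
negative values task-related decrease (desynchronization).  Channel TRPs
are aggregated into five cortical areas x two hemispheres using fixed
10-10 electrode groups, and analyzed with repeated-measures ANOVA
(CONDITION x AREA x HEMISPHERE) plus Bonferroni post-hocs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import welch

from .containers import EEGRecording
from .stats import bonferroni_posthoc, rm_anova  # noqa: F401  (re-exported surface)

__all__ = [
    "BandDefinition",
    "DEFAULT_BANDS",
    "REGION_CHANNELS",
    "welch_psd",
    "band_power",
    "compute_trp",
    "band_power_table",
    "aggregate_regions",
    "channel_region",
    "rm_anova",
    "bonferroni_posthoc",
]


@dataclass(frozen=True)
class BandDefinition:
    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not 0 < self.lo < self.hi:
            raise ValueError("need 0 < lo < hi")


DEFAULT_BANDS = (
    BandDefinition("delta", 1.0, 3.5),
    BandDefinition("theta", 4.0, 7.5),
    BandDefinition("alpha", 8.0, 13.5),
    BandDefinition("beta", 14.0, 29.0),
)

# Left-hemisphere area memberships; right = corresponding even-numbered names.
_LEFT_REGIONS = {
    "frontal": ["Fp1", "AF3", "AF7", "F1", "F3", "F5", "F7", "FC1", "FC3"],
    "central": ["FC5", "C1", "C3", "C5"],
    "temporal": ["FT7", "T7", "TP7", "CP5", "P5"],
    "parietal": ["CP1", "CP3", "P1", "P3"],
    "occipital": ["PO3", "PO7", "P7", "O1"],
}


def _mirror(label: str) -> str:
    """Left (odd) 10-10 name -> homologous right (even) name."""
    head = label.rstrip("0123456789")
    num = int(label[len(head):])
    return f"{head}{num + 1}"


REGION_CHANNELS: dict[tuple[str, str], list[str]] = {}
for _area, _chs in _LEFT_REGIONS.items():
    REGION_CHANNELS[(_area, "left")] = list(_chs)
    REGION_CHANNELS[(_area, "right")] = [_mirror(c) for c in _chs]


def channel_region(label: str) -> tuple[str, str] | None:
    """(area, hemisphere) of an electrode, or None if outside the groups."""
    for key, chs in REGION_CHANNELS.items():
        if label in chs:
            return key
    return None


def welch_psd(
    rec: EEGRecording, *, nperseg: int = 500, noverlap: int = 250, window: str = "hann"
) -> tuple[np.ndarray, np.ndarray]:
    """Per-channel one-sided PSD in uV^2/Hz by Welch segment averaging."""
    if rec.n_samples < nperseg:
        raise ValueError(f"record shorter than one Welch window ({nperseg} samples)")
    freqs, psd = welch(
        rec.data, fs=rec.fs, window=window, nperseg=nperseg, noverlap=noverlap, axis=1
    )
    return freqs, psd


def band_power(freqs: np.ndarray, psd: np.ndarray, band: BandDefinition) -> np.ndarray:
    """Trapezoidal band-integrated power, boundary bins linearly interpolated.

    ``psd`` may be (n_freqs,) or (n_channels, n_freqs); returns power in
    uV^2 with matching leading shape.
    """
    if band.lo >= freqs[-1] or band.hi <= freqs[0]:
        raise ValueError(f"band {band.name} outside spectral support")
    if band.hi > freqs[-1]:
        raise ValueError(f"band {band.name} exceeds Nyquist support")
    psd = np.atleast_2d(psd)
    inner = (freqs > band.lo) & (freqs < band.hi)
    grid = np.concatenate([[band.lo], freqs[inner], [band.hi]])
    vals = np.empty((psd.shape[0], grid.size))
    vals[:, 1:-1] = psd[:, inner]
    vals[:, 0] = np.array([np.interp(band.lo, freqs, p) for p in psd])
    vals[:, -1] = np.array([np.interp(band.hi, freqs, p) for p in psd])
    power = np.trapezoid(vals, grid, axis=1)
    return power if power.size > 1 else power[0]


def compute_trp(activation_power, reference_power, log_base: float = 10.0):
    """Log band-power change from rest: log(activation) - log(reference)."""
    act = np.asarray(activation_power, dtype=float)
    ref = np.asarray(reference_power, dtype=float)
    if np.any(act <= 0) or np.any(ref <= 0):
        raise ValueError("band powers must be positive")
    out = (np.log(act) - np.log(ref)) / np.log(log_base)
    return out if out.ndim else float(out)


def band_power_table(
    rec: EEGRecording,
    *,
    participant: str = "",
    run: str = "",
    condition: str = "",
    bands=DEFAULT_BANDS,
) -> pd.DataFrame:
    """Tidy per-channel band powers of one condition-tagged recording."""
    freqs, psd = welch_psd(rec)
    rows = []
    for band in bands:
        pw = np.atleast_1d(band_power(freqs, psd, band))
        for ch, p in zip(rec.channel_labels, pw):
            reg = channel_region(ch)
            rows.append(
                {
                    "participant": participant,
                    "run": run,
                    "condition": condition,
                    "channel": ch,
                    "band": band.name,
                    "power_uv2": p,
                    "log_power": np.log10(p) if p > 0 else np.nan,
                    "area": reg[0] if reg else None,
                    "hemisphere": reg[1] if reg else None,
                }
            )
    return pd.DataFrame(rows)


def trp_table(power_df: pd.DataFrame, reference_condition: str = "REST") -> pd.DataFrame:
    """Attach TRP values: per-channel log power minus the rest-reference.

    The reference is the first rest block of the same participant (first
    run in sort order when several rest runs exist).  Condition-wise TRP is
    the mean over runs of the same condition.
    """
    out = []
    for participant, sub in power_df.groupby("participant"):
        rest = sub[sub["condition"] == reference_condition]
        if rest.empty:
            continue
        first_run = sorted(rest["run"].unique())[0]
        ref = rest[rest["run"] == first_run].set_index(["channel", "band"])["log_power"]
        task = sub[sub["condition"] != reference_condition].copy()
        task["trp"] = task.apply(
            lambda r: r["log_power"] - ref.loc[(r["channel"], r["band"])], axis=1
        )
        out.append(task)
    if not out:
        raise ValueError("no participant has a rest reference")
    tidy = pd.concat(out, ignore_index=True)
    cond = (
        tidy.groupby(["participant", "condition", "channel", "band", "area", "hemisphere"],
                     dropna=False)["trp"]
        .mean()
        .reset_index()
    )
    return cond


def aggregate_regions(trp_df: pd.DataFrame) -> pd.DataFrame:
    """Mean TRP per (participant, condition, band, area, hemisphere).

    Channels outside the printed area groups are excluded; a missing listed
    channel simply reduces the mean's support (warned upstream at ingest).
    """
    sub = trp_df.dropna(subset=["area", "hemisphere"])
    return (
        sub.groupby(["participant", "condition", "band", "area", "hemisphere"])["trp"]
        .mean()
        .reset_index()
    )
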