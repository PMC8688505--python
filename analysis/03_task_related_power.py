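#!/usr/bin/env python
"""Task-related power on synthetic rest/task pairs.

Shows that a tenfold task alpha-power gain is recovered as a frontal-alpha
TRP of +1.0 on the log10 scale, then computes the cohort TRP table with its
CONDITION x AREA x HEMISPHERE repeated-measures ANOVA.
"""

from pathlib import Path

import numpy as np

from microdyn.montage import standard_1010_montage
from microdyn.pipeline import StudyConfig, run_study
from microdyn.synth import SynthConfig, make_template_maps, simulate_eeg, simulate_label_sequence
from microdyn.trp import REGION_CHANNELS, BandDefinition, band_power, compute_trp, welch_psd

OUT = Path(__file__).resolve().parents[1] / "results"


def tenfold_demo() -> None:
    mont = standard_1010_montage()
    maps = make_template_maps(mont, 7, seed=3)
    frontal = REGION_CHANNELS[("frontal", "left")] + REGION_CHANNELS[("frontal", "right")]
    idx = [mont.index(ch) for ch in frontal]
    alpha = BandDefinition("alpha", 8.0, 13.5)
    powers = {}
    for name, gain in (("rest", 1.0), ("task", 10.0)):
        cfg = SynthConfig(n_channels=63, fs=250.0, k_true=7, snr=5.0 * np.sqrt(gain),
                          amplitude_uv=15.0 * np.sqrt(gain), seed=9)
        labels = simulate_label_sequence(cfg, 30000)
        rec = simulate_eeg(maps, labels, cfg, montage=mont)
        freqs, psd = welch_psd(rec)
        powers[name] = np.atleast_1d(band_power(freqs, psd, alpha))[idx]
    trp = compute_trp(powers["task"], powers["rest"])
    print(f"Tenfold alpha-power task vs rest -> frontal alpha TRP = {trp.mean():.4f} "
          "(expected 1.0 on the log10 scale)")


def cohort_trp() -> None:
    cfg = StudyConfig(n_participants=4, run_duration_s=30.0, seed=0, kmeans_restarts=5)
    report = run_study(cfg, compute_hurst=False)
    OUT.mkdir(exist_ok=True)
    report.trp_table.to_csv(OUT / "trp_table.csv", index=False)
    report.trp_anova.to_csv(OUT / "trp_anova_alpha.csv", index=False)
    alpha = report.trp_table[report.trp_table["band"] == "alpha"]
    cond_means = alpha.groupby("condition")["trp"].mean().sort_values()
    print("\nCohort mean alpha TRP by condition (most negative = strongest")
    print("task-related desynchronization; IG was planted with the largest drop):")
    print(cond_means.to_string())
    print("\nCONDITION x AREA x HEMISPHERE rm-ANOVA on alpha TRP:")
    print(report.trp_anova[["effect", "F", "df1", "df2", "p", "partial_eta_sq"]]
          .to_string(index=False))


if __name__ == "__main__":
    tenfold_demo()
    cohort_trp()
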