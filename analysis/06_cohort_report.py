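#!/usr/bin/env python
"""Full cohort analysis: the end-to-end condition contrast.

Runs the complete pipeline (synthesis -> preprocessing -> TRP ->
microstates -> sequence dynamics -> cohort statistics) and reports the
headline contrast: idea generation (IG) shows the highest entropy rate and
the lowest mean Hurst exponent of all conditions, because its planted
switching is the most random.
"""

from pathlib import Path

from microdyn.pipeline import StudyConfig, run_study

OUT = Path(__file__).resolve().parents[1] / "results" / "cohort"


def main() -> None:
    cfg = StudyConfig(n_participants=5, run_duration_s=60.0, seed=2, kmeans_restarts=5)
    report = run_study(cfg, out_dir=OUT)
    means = report.seq_table.groupby("condition")[["entropy_rate", "hurst_mean"]].mean()
    print("Cohort means by condition:")
    print(means.round(4).to_string())
    print("\nEntropy-rate condition ANOVA:")
    print(report.entropy_anova[["effect", "F", "df1_gg", "df2_gg", "p", "partial_eta_sq"]]
          .round(4).to_string(index=False))
    print("\nHurst condition ANOVA:")
    print(report.hurst_anova[["effect", "F", "df1_gg", "df2_gg", "p", "partial_eta_sq"]]
          .round(4).to_string(index=False))
    ig_h = means.loc["IG", "entropy_rate"]
    ig_hu = means.loc["IG", "hurst_mean"]
    print(f"\nIG entropy rate {ig_h:.3f} bits/sample is the cohort maximum: "
          f"{bool(ig_h == means['entropy_rate'].max())}")
    print(f"IG mean Hurst {ig_hu:.3f} is the cohort minimum: "
          f"{bool(ig_hu == means['hurst_mean'].min())}")
    print(f"\nAll tables written under {OUT}")


if __name__ == "__main__":
    main()
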