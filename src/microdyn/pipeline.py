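"""Cohort orchestration: synthesis/ingest -> preprocessing -> band power ->
microstates -> sequence dynamics -> cohort statistics.

A study consists of participants, each with condition-tagged runs drawn
from the vocabulary {REST, PU, IG, RIG, IE, RIE} (rest plus five design
activities: problem understanding, idea generation, rating idea
generation, idea evaluation, rating idea evaluation).  ``run_study``
executes every stage in order, deterministically for a given seed, and
returns a :class:`CohortReport` with the task-related-power tables and
ANOVA, the microstate-parameter tables and CONDITION x CLASS ANOVA, and
the sequence-dynamics tables (entropy rate, AIF first-peak latency, mean
Hurst exponent) with one-way condition ANOVAs and Bonferroni post-hocs.

The synthetic-study generator plants condition-specific dynamics: per
condition the label dwell time, the transition-bias toward a preferred
successor class (lower bias = more random switching = higher entropy
rate), the long-range gate exponent (larger = higher mean Hurst), and an
alpha-carrier power gain relative to rest (TRP contrast).
"""

from __future__ import annotations

import json
import warnings
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import microstates as ms
from . import seqstats, synth, trp
from .containers import EEGRecording
from .montage import Montage, standard_1010_montage
from .preprocess import PreprocessConfig, QCReport, run_preprocess
from .stats import bonferroni_posthoc, rm_anova

__all__ = [
    "CONDITIONS",
    "ConditionSpec",
    "StudyConfig",
    "StudyLayout",
    "CohortReport",
    "default_condition_specs",
    "simulate_study",
    "run_study",
    "condition_anova_seqstats",
    "load_study_config",
]

CONDITIONS = ["REST", "PU", "IG", "RIG", "IE", "RIE"]


@dataclass(frozen=True)
class ConditionSpec:
    """Planted dynamics of one condition in the synthetic study."""

    mean_duration_ms: float = 50.0
    transition_bias: float = 0.3  # 0 = uniform jumps (max switching entropy)
    gate_hurst: float = 0.7  # long-range memory of the class-group gate
    alpha_gain: float = 1.0  # carrier power gain vs rest


def default_condition_specs() -> dict[str, ConditionSpec]:
    """Study conditions: idea generation (IG) switches most randomly and
    carries the least long-range memory; the rating conditions (RIG/RIE)
    are the most structured; task alpha power drops below rest, most
    strongly during IG."""
    return {
        "REST": ConditionSpec(60.0, 0.40, 0.75, 1.00),
        "PU": ConditionSpec(55.0, 0.35, 0.72, 0.90),
        "IG": ConditionSpec(45.0, 0.00, 0.50, 0.70),
        "RIG": ConditionSpec(60.0, 0.50, 0.80, 0.95),
        "IE": ConditionSpec(50.0, 0.15, 0.60, 0.80),
        "RIE": ConditionSpec(60.0, 0.50, 0.80, 0.95),
    }


@dataclass
class StudyConfig:
    """Everything needed to synthesize and analyze one cohort."""

    n_participants: int = 5
    run_duration_s: float = 60.0
    fs: float = 500.0
    n_classes: int = 7
    snr: float = 3.0
    carrier_freq_hz: float = 10.0
    amplitude_uv: float = 15.0
    seed: int = 0
    conditions: dict[str, ConditionSpec] = field(default_factory=default_condition_specs)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    kmeans_restarts: int = 10
    forced_k: int = 7
    k_range: tuple[int, int] = (2, 10)
    report_optimal_k: bool = False
    entropy_history_k: int = 6
    aif_max_lag_ms: float = 200.0
    trp_log_base: float = 10.0


@dataclass
class StudyLayout:
    """participants -> list of (condition, run, EEGRecording)."""

    recordings: dict[str, list[tuple[str, str, EEGRecording]]]
    montage: Montage

    def __post_init__(self) -> None:
        for pid, items in self.recordings.items():
            for cond, run, rec in items:
                if cond not in CONDITIONS:
                    raise ValueError(f"unknown condition tag {cond!r} for {pid}")


@dataclass
class CohortReport:
    trp_table: pd.DataFrame | None = None
    trp_anova: pd.DataFrame | None = None
    trp_posthoc: pd.DataFrame | None = None
    microstate_params: pd.DataFrame | None = None
    params_anova: dict[str, pd.DataFrame] = field(default_factory=dict)
    seq_table: pd.DataFrame | None = None
    entropy_anova: pd.DataFrame | None = None
    entropy_posthoc: pd.DataFrame | None = None
    hurst_anova: pd.DataFrame | None = None
    hurst_posthoc: pd.DataFrame | None = None
    qc_summary: pd.DataFrame | None = None
    optimal_k: dict[tuple[str, str, str], int] = field(default_factory=dict)
    excluded_from_trp: list[tuple[str, str]] = field(default_factory=list)
    log: list[dict] = field(default_factory=list)


def _bias_transition_matrix(k: int, bias: float) -> np.ndarray:
    """Off-diagonal jump matrix mixing uniform and cyclic-successor mass."""
    if k == 1:
        return np.ones((1, 1))
    p = (1.0 - bias) * np.full((k, k), 1.0 / (k - 1))
    np.fill_diagonal(p, 0.0)
    for i in range(k):
        p[i, (i + 1) % k] += bias
    return p / p.sum(axis=1, keepdims=True)


def simulate_study(cfg: StudyConfig) -> StudyLayout:
    """Synthesize one cohort with per-participant template maps."""
    montage = standard_1010_montage()
    n_samples = int(round(cfg.run_duration_s * cfg.fs))
    recordings: dict[str, list[tuple[str, str, EEGRecording]]] = {}
    for p in range(cfg.n_participants):
        pid = f"sub{p + 1:02d}"
        maps = synth.make_template_maps(montage, cfg.n_classes, seed=cfg.seed + 7919 * (p + 1))
        items = []
        for ci, cond in enumerate(cfg.conditions):
            spec = cfg.conditions[cond]
            run_seed = cfg.seed + 104729 * (p + 1) + 101 * (ci + 1)
            scfg = synth.SynthConfig(
                n_channels=montage.n_channels,
                fs=cfg.fs,
                k_true=cfg.n_classes,
                mean_duration_ms=spec.mean_duration_ms,
                transition_matrix=_bias_transition_matrix(cfg.n_classes, spec.transition_bias),
                carrier_freq_hz=cfg.carrier_freq_hz,
                snr=cfg.snr,
                amplitude_uv=cfg.amplitude_uv * np.sqrt(spec.alpha_gain),
                seed=run_seed,
            )
            labels = synth.simulate_gated_label_sequence(
                scfg, n_samples, gate_hurst=spec.gate_hurst
            )
            rec = synth.simulate_eeg(
                maps, labels, scfg, montage=montage, condition=cond, run="run1"
            )
            items.append((cond, "run1", rec))
        recordings[pid] = items
    return StudyLayout(recordings=recordings, montage=montage)


def _stage(report: CohortReport, name: str, pid: str = "", extra: dict | None = None):
    report.log.append({"stage": name, "participant": pid, **(extra or {})})


def condition_anova_seqstats(df: pd.DataFrame, dv: str) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One-way repeated-measures condition ANOVA with Bonferroni pairs.

    Participants with missing cells are excluded listwise.
    """
    wide = df.groupby(["participant", "condition"])[dv].mean().unstack("condition")
    complete = wide.dropna()
    if complete.shape[0] < 3:
        raise ValueError("need at least 3 complete participants")
    long = complete.stack().rename(dv).reset_index()
    anova = rm_anova(long, dv, "participant", ["condition"])
    posthoc = bonferroni_posthoc(long, dv, "participant", "condition")
    return anova, posthoc


def run_study(
    cfg: StudyConfig,
    layout: StudyLayout | None = None,
    *,
    out_dir=None,
    compute_hurst: bool = True,
) -> CohortReport:
    """Execute the full analysis chain on a (synthetic or ingested) cohort.

    Stage failures abort with an error naming the stage; partial outputs
    written so far are preserved when ``out_dir`` is given.  Rerunning with
    the same config seeds is bit-identical.
    """
    report = CohortReport()
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    if layout is None:
        try:
            layout = simulate_study(cfg)
        except Exception as err:
            raise RuntimeError(f"stage 'simulate_study' failed: {err}") from err
        _stage(report, "simulate_study", extra={"seed": cfg.seed})

    # ---- preprocessing -------------------------------------------------
    clean: dict[str, list[tuple[str, str, EEGRecording]]] = {}
    qc_rows = []
    for pid, items in layout.recordings.items():
        clean[pid] = []
        for cond, run, rec in items:
            try:
                crec, qc = run_preprocess(rec, cfg.preprocess)
            except Exception as err:
                raise RuntimeError(
                    f"stage 'preprocess' failed for {pid}/{cond}/{run}: {err}"
                ) from err
            clean[pid].append((cond, run, crec))
            qc_rows.append(
                {
                    "participant": pid,
                    "condition": cond,
                    "run": run,
                    "n_bad_channels": len(qc.bad_global_channels),
                    "n_bad_segments": len(qc.bad_segments),
                    "n_local_interpolated": len(qc.interpolated_local),
                    "fraction_rejected": qc.fraction_rejected,
                }
            )
        _stage(report, "preprocess", pid)
    report.qc_summary = pd.DataFrame(qc_rows)

    # ---- task-related power --------------------------------------------
    try:
        power_frames = []
        for pid, items in clean.items():
            if not any(cond == "REST" for cond, _, _ in items):
                report.excluded_from_trp.append((pid, "missing REST reference"))
                continue
            for cond, run, crec in items:
                power_frames.append(
                    trp.band_power_table(crec, participant=pid, run=run, condition=cond)
                )
        power_df = pd.concat(power_frames, ignore_index=True)
        trp_df = trp.trp_table(power_df, reference_condition="REST")
        region_df = trp.aggregate_regions(trp_df)
        report.trp_table = region_df
        alpha = region_df[region_df["band"] == "alpha"]
        if alpha["participant"].nunique() >= 3:
            report.trp_anova = rm_anova(
                alpha, "trp", "participant", ["condition", "area", "hemisphere"]
            )
            report.trp_posthoc = bonferroni_posthoc(alpha, "trp", "participant", "condition")
    except Exception as err:
        raise RuntimeError(f"stage 'trp' failed: {err}") from err
    _stage(report, "trp")

    # ---- microstates ----------------------------------------------------
    seq_rows = []
    param_rows = []
    for pid, items in clean.items():
        models = []
        peak_sets = []
        for cond, run, crec in items:
            try:
                g = ms.gfp(crec)
                peaks = ms.gfp_peaks(g)
                x = crec.data.T[peaks]
                fit_seed = (cfg.seed + zlib.crc32(f"{pid}/{cond}/{run}".encode())) % (2**31 - 1)
                model = ms.modified_kmeans(
                    x,
                    cfg.forced_k,
                    n_restarts=cfg.kmeans_restarts,
                    seed=fit_seed,
                    channel_labels=list(crec.channel_labels),
                )
                if cfg.report_optimal_k:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        k_star, _ = ms.select_optimal_k(
                            x,
                            range(cfg.k_range[0], cfg.k_range[1] + 1),
                            n_restarts=max(cfg.kmeans_restarts // 2, 3),
                            seed=cfg.seed,
                        )
                    report.optimal_k[(pid, cond, run)] = k_star
            except Exception as err:
                raise RuntimeError(
                    f"stage 'microstate_fit' failed for {pid}/{cond}/{run}: {err}"
                ) from err
            models.append(model)
            peak_sets.append((cond, run, crec))
        try:
            group_model, _perms = ms.align_maps_group(models)
        except Exception as err:
            raise RuntimeError(f"stage 'map_alignment' failed for {pid}: {err}") from err
        for cond, run, crec in peak_sets:
            try:
                seq = ms.backfit(crec, group_model, condition=cond)
                params = ms.microstate_parameters(seq)
                dyn = seqstats.sequence_dynamics(
                    seq,
                    history_k=cfg.entropy_history_k,
                    max_lag_ms=cfg.aif_max_lag_ms,
                    compute_hurst=compute_hurst,
                )
            except Exception as err:
                raise RuntimeError(
                    f"stage 'seqstats' failed for {pid}/{cond}/{run}: {err}"
                ) from err
            for k in range(params.n_classes):
                param_rows.append(
                    {
                        "participant": pid,
                        "condition": cond,
                        "run": run,
                        "class": k,
                        "duration_ms": params.duration_ms[k],
                        "occurrence_hz": params.occurrence_hz[k],
                        "coverage": params.coverage[k],
                    }
                )
            seq_rows.append(
                {
                    "participant": pid,
                    "condition": cond,
                    "run": run,
                    "entropy_rate": dyn.entropy_rate,
                    "aif_first_peak_ms": dyn.first_peak_latency_ms,
                    "hurst_mean": dyn.hurst_mean,
                }
            )
        _stage(report, "microstates", pid)

    report.microstate_params = pd.DataFrame(param_rows)
    report.seq_table = pd.DataFrame(seq_rows)

    # ---- cohort statistics ---------------------------------------------
    try:
        if report.microstate_params["participant"].nunique() >= 3:
            for dv in ("duration_ms", "occurrence_hz", "coverage"):
                sub = report.microstate_params.dropna(subset=[dv])
                # listwise exclusion: keep participants with a full 6 x 7 grid
                cells = sub.groupby("participant")[["condition", "class"]].nunique()
                full = cells[(cells["condition"] == 6) & (cells["class"] == 7)].index
                sub = sub[sub["participant"].isin(full)]
                if sub["participant"].nunique() < 3:
                    report.log.append(
                        {"stage": "cohort_stats", "skipped_anova": dv,
                         "reason": "fewer than 3 complete participants"}
                    )
                    continue
                try:
                    report.params_anova[dv] = rm_anova(
                        sub, dv, "participant", ["condition", "class"]
                    )
                except ValueError as err:
                    report.log.append(
                        {"stage": "cohort_stats", "skipped_anova": dv, "reason": str(err)}
                    )
        if report.seq_table["participant"].nunique() >= 3:
            dvs = ["entropy_rate"] + (["hurst_mean"] if compute_hurst else [])
            for dv in dvs:
                try:
                    anova, posthoc = condition_anova_seqstats(report.seq_table, dv)
                except ValueError as err:
                    report.log.append(
                        {"stage": "cohort_stats", "skipped_anova": dv, "reason": str(err)}
                    )
                    continue
                if dv == "entropy_rate":
                    report.entropy_anova, report.entropy_posthoc = anova, posthoc
                else:
                    report.hurst_anova, report.hurst_posthoc = anova, posthoc
    except Exception as err:
        raise RuntimeError(f"stage 'cohort_stats' failed: {err}") from err
    _stage(report, "cohort_stats")

    if out is not None:
        _persist(report, out)
    return report


def _persist(report: CohortReport, out: Path) -> None:
    for name in (
        "trp_table",
        "trp_anova",
        "trp_posthoc",
        "microstate_params",
        "seq_table",
        "entropy_anova",
        "entropy_posthoc",
        "hurst_anova",
        "hurst_posthoc",
        "qc_summary",
    ):
        df = getattr(report, name)
        if df is not None:
            df.to_csv(out / f"{name}.csv", index=False)
    for dv, df in report.params_anova.items():
        df.to_csv(out / f"params_anova_{dv}.csv", index=False)
    (out / "log.json").write_text(json.dumps(report.log, indent=1))


def load_study_config(path) -> StudyConfig:
    """Build a StudyConfig from a YAML file (missing keys -> defaults)."""
    import yaml

    raw = yaml.safe_load(Path(path).read_text()) or {}
    cond_raw = raw.pop("conditions", None)
    pre_raw = raw.pop("preprocess", None)
    cfg = StudyConfig(**raw)
    if cond_raw:
        cfg.conditions = {
            name: ConditionSpec(**spec) for name, spec in cond_raw.items()
        }
    if pre_raw:
        cfg.preprocess = PreprocessConfig(**pre_raw)
    return cfg
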