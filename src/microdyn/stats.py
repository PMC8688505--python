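"""Balanced within-subject (repeated-measures) factorial ANOVA.

Implements the classical univariate mixed-model decomposition for designs
where every factor is within-subject and every subject contributes one
observation per cell (replicates are averaged first).  For each effect E
(a main effect or interaction) the subject-level data are reduced to
orthonormal contrast scores Z; then

    F = (n * ||mean(Z)||^2 / d) / (SS_within / (d (n-1)))

with d the effect degrees of freedom.  Sphericity of each effect is checked
with Mauchly's W; when rejected (alpha = 0.05) the Greenhouse-Geisser
epsilon  eps = tr(S)^2 / (d * tr(S^2))  shrinks both degrees of freedom.
Partial eta^2 = SS_effect / (SS_effect + SS_error) is reported per effect.

Post-hoc paired comparisons use paired t-tests with Bonferroni correction.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["rm_anova", "bonferroni_posthoc"]


def _helmert_contrast(levels: int) -> np.ndarray:
    """Orthonormal (levels-1) x levels contrast matrix with zero row sums."""
    c = np.zeros((levels - 1, levels))
    for i in range(levels - 1):
        c[i, : i + 1] = 1.0
        c[i, i + 1] = -(i + 1)
        c[i] /= np.linalg.norm(c[i])
    return c


def _effect_contrast(factors_in_effect, all_factors, level_counts) -> np.ndarray:
    """Kronecker contrast over the full cell grid for one effect."""
    mat = np.ones((1, 1))
    for f in all_factors:
        if f in factors_in_effect:
            part = _helmert_contrast(level_counts[f])
        else:
            part = np.full((1, level_counts[f]), 1.0 / level_counts[f])
        mat = np.kron(mat, part)
    return mat


def _mauchly(z: np.ndarray) -> tuple[float, float]:
    """Mauchly's sphericity test on contrast scores z (n x d)."""
    n, d = z.shape
    if d < 2:
        return np.nan, 1.0
    if n - 1 <= d:
        return np.nan, 0.0  # cannot test; treat sphericity as violated
    s = np.cov(z, rowvar=False, ddof=1)
    eig = np.linalg.eigvalsh(s)
    eig = np.clip(eig, 1e-300, None)
    w = np.exp(np.log(eig).sum() - d * np.log(eig.mean()))
    f = n - 1
    chi2 = -(f - (2 * d**2 + d + 2) / (6.0 * d)) * np.log(max(w, 1e-300))
    dof = d * (d + 1) // 2 - 1
    p = float(sps.chi2.sf(chi2, dof))
    return float(w), p


def _gg_epsilon(z: np.ndarray) -> float:
    d = z.shape[1]
    if d < 2:
        return 1.0
    s = np.cov(z, rowvar=False, ddof=1)
    denom = d * np.trace(s @ s)
    if denom == 0:  # degenerate (e.g. all-equal data): no sphericity issue
        return 1.0
    eps = np.trace(s) ** 2 / denom
    return float(np.clip(eps, 1.0 / d, 1.0))


def rm_anova(
    df: pd.DataFrame,
    dv: str,
    subject: str,
    within: list[str],
    *,
    sphericity_alpha: float = 0.05,
) -> pd.DataFrame:
    """Fully within-subject factorial repeated-measures ANOVA.

    Parameters
    ----------
    df : tidy DataFrame with one row per observation.
    dv : name of the dependent-variable column.
    subject : name of the subject identifier column.
    within : names of the within-subject factor columns (1-3 factors).

    Returns
    -------
    DataFrame with one row per effect: F, df1, df2, p (uncorrected),
    Mauchly W and p, GG epsilon, GG-corrected df and p, the p-value to
    report (GG-corrected when Mauchly rejects at ``sphericity_alpha``),
    and partial eta squared.

    Raises
    ------
    ValueError for unbalanced designs or fewer than 3 subjects.
    """
    level_values = {f: sorted(df[f].unique()) for f in within}
    level_counts = {f: len(level_values[f]) for f in within}
    subjects = sorted(df[subject].unique())
    n = len(subjects)
    if n < 3:
        raise ValueError("need at least 3 subjects")

    cell = df.groupby([subject, *within], sort=True)[dv].mean().unstack(within)
    # full cell grid, subjects x cells in factor-major order
    full_cols = pd.MultiIndex.from_product([level_values[f] for f in within], names=within) \
        if len(within) > 1 else pd.Index(level_values[within[0]], name=within[0])
    try:
        cell = cell.reindex(index=subjects, columns=full_cols)
    except Exception as err:  # pragma: no cover
        raise ValueError("design is not a full factorial") from err
    if cell.isna().any().any():
        raise ValueError("unbalanced design: every subject needs every cell")
    y = cell.to_numpy(dtype=float)

    rows = []
    for r in range(1, len(within) + 1):
        for combo in itertools.combinations(within, r):
            c = _effect_contrast(set(combo), within, level_counts)
            z = y @ c.T  # (n, d)
            d = z.shape[1]
            zbar = z.mean(axis=0)
            ss_eff = n * (zbar**2).sum()
            ss_err = ((z - zbar) ** 2).sum()
            df1, df2 = d, d * (n - 1)
            ms_eff = ss_eff / df1
            ms_err = ss_err / df2
            if ms_err > 0:
                f_val = ms_eff / ms_err
            else:
                # degenerate: no within-subject spread; all-equal data -> F = 0
                f_val = 0.0 if np.isclose(ms_eff, 0.0) else np.inf
            p_unc = float(sps.f.sf(f_val, df1, df2))
            w, p_mauchly = _mauchly(z)
            eps = _gg_epsilon(z)
            df1_gg, df2_gg = df1 * eps, df2 * eps
            p_gg = float(sps.f.sf(f_val, df1_gg, df2_gg))
            violated = d > 1 and p_mauchly < sphericity_alpha
            rows.append(
                {
                    "effect": " x ".join(combo),
                    "F": f_val,
                    "df1": df1,
                    "df2": df2,
                    "p_uncorrected": p_unc,
                    "mauchly_W": w,
                    "mauchly_p": p_mauchly,
                    "gg_epsilon": eps,
                    "df1_gg": df1_gg,
                    "df2_gg": df2_gg,
                    "p_gg": p_gg,
                    "sphericity_violated": violated,
                    "p": p_gg if violated else p_unc,
                    "partial_eta_sq": ss_eff / (ss_eff + ss_err) if ss_eff + ss_err > 0 else np.nan,
                }
            )
    return pd.DataFrame(rows)


def bonferroni_posthoc(
    df: pd.DataFrame,
    dv: str,
    subject: str,
    factor: str,
    *,
    pairs: list[tuple] | None = None,
) -> pd.DataFrame:
    """Paired t-tests over factor-level pairs, Bonferroni-adjusted.

    ``p_adjusted = min(1, p_raw * n_comparisons)``.  Identical paired
    samples yield t = 0 and adjusted p = 1.
    """
    levels = sorted(df[factor].unique())
    if pairs is None:
        pairs = list(itertools.combinations(levels, 2))
    m = len(pairs)
    wide = df.groupby([subject, factor])[dv].mean().unstack(factor)
    if wide.shape[0] < 2:
        raise ValueError("need at least 2 subjects for paired tests")
    rows = []
    for a, b in pairs:
        x, yv = wide[a].to_numpy(), wide[b].to_numpy()
        diff = x - yv
        if np.allclose(diff, diff[0]) and np.isclose(diff[0], 0):
            t_val, p_raw = 0.0, 1.0
        else:
            t_val, p_raw = sps.ttest_rel(x, yv)
        rows.append(
            {
                "level_a": a,
                "level_b": b,
                "mean_diff": float(np.mean(diff)),
                "t": float(t_val),
                "p_raw": float(p_raw),
                "p_bonferroni": float(min(1.0, p_raw * m)),
            }
        )
    return pd.DataFrame(rows)
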