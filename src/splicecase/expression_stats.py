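"""Cohort z-scores, low-expression filtering, 2^-ddCt quantification and
simple pedigree group comparisons.

The z-score places a single patient expression value (TPM) against a healthy
control cohort: z = (value - mean) / sd, with a two-tailed p from the
standard normal.  Both an empirical percentile (% of controls <= value) and
the normal-theory percentile are reported, since small cohorts make the two
visibly different.

Relative qPCR quantification follows the 2^-ddCt method: replicates are
averaged per (sample, gene), dCt = Ct(target) - Ct(reference) per sample,
ddCt = dCt(sample) - dCt(calibrator), relative expression = 2^-ddCt.
Replicate standard errors are propagated through the exponent.

The t-test and one-way ANOVA are deliberately thin textbook-formula
implementations (pooled variance; between/within mean squares) with p-values
from scipy's t and F distributions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

LOG2 = math.log(2.0)


@dataclass(frozen=True)
class ExpressionStat:
    value_tpm: float
    control_mean_tpm: float
    control_sd_tpm: float
    z: float
    p_two_tailed: float
    percentile_normal: float
    percentile_empirical: float | None
    n_controls: int | None


@dataclass(frozen=True)
class DdctResult:
    sample: str
    delta_ct_sample: float
    delta_ct_calibrator: float
    ddct: float
    relative_expression: float
    percent_change: float
    replicate_se: float


def expression_zscore(
    value: float,
    controls=None,
    mean: float | None = None,
    sd: float | None = None,
    n: int | None = None,
) -> ExpressionStat:
    """Standardize one expression value against a control cohort.

    Supply either raw ``controls`` (mean/sd use the n-1 sample estimator and
    the empirical percentile is computed) or summary ``mean``/``sd``/``n``.
    """
    empirical = None
    if controls is not None:
        controls = np.asarray(controls, dtype=float)
        if controls.size < 2:
            raise ValueError("need at least 2 control values")
        mean = float(np.mean(controls))
        sd = float(np.std(controls, ddof=1))
        n = int(controls.size)
        empirical = 100.0 * float(np.sum(controls <= value)) / n
    if mean is None or sd is None:
        raise ValueError("supply raw controls or mean and sd")
    if sd <= 0:
        raise ValueError("control sd must be positive")
    z = (value - mean) / sd
    p = 2.0 * float(stats.norm.sf(abs(z)))
    return ExpressionStat(
        value_tpm=float(value),
        control_mean_tpm=float(mean),
        control_sd_tpm=float(sd),
        z=float(z),
        p_two_tailed=min(p, 1.0),
        percentile_normal=100.0 * float(stats.norm.cdf(z)),
        percentile_empirical=empirical,
        n_controls=n,
    )


def low_expression_filter(
    tpm_matrix: pd.DataFrame,
    tpm_threshold: float = 1.0,
    sample_fraction: float = 0.9,
) -> list:
    """Gene ids retained after the low-expression rule.

    A gene is removed iff *strictly more than* ``sample_fraction`` of samples
    have TPM <= ``tpm_threshold`` (so a gene low in exactly 90% of samples is
    retained under the default).
    """
    if tpm_matrix.empty:
        raise ValueError("empty TPM matrix")
    low_frac = (tpm_matrix <= tpm_threshold).mean(axis=1)
    return list(tpm_matrix.index[low_frac <= sample_fraction])


def ddct(
    ct_table: pd.DataFrame,
    target_gene: str,
    reference_gene: str,
    calibrator_sample: str,
) -> dict[str, DdctResult]:
    """Per-sample 2^-ddCt relative expression against a calibrator sample.

    ``ct_table`` columns: sample, gene, replicate, ct.  Replicates are
    averaged first; the replicate standard error of each mean is propagated
    into the relative-expression SE (SE_RE = RE * ln2 * SE_ddCt).
    """
    required = {"sample", "gene", "replicate", "ct"}
    if not required <= set(ct_table.columns):
        raise ValueError(f"Ct table must have columns {sorted(required)}")

    def mean_se(sample, gene):
        vals = ct_table[(ct_table["sample"] == sample)
                        & (ct_table["gene"] == gene)]["ct"].to_numpy(float)
        if vals.size == 0:
            raise ValueError(f"sample {sample!r} lacks Ct values for gene {gene!r}")
        se = float(np.std(vals, ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else 0.0
        return float(np.mean(vals)), se

    samples = list(dict.fromkeys(ct_table["sample"]))
    if calibrator_sample not in samples:
        raise ValueError(f"calibrator sample {calibrator_sample!r} not in table")

    d_cal, se_cal = _delta_ct(mean_se, calibrator_sample, target_gene, reference_gene)
    out = {}
    for s in samples:
        d_s, se_s = _delta_ct(mean_se, s, target_gene, reference_gene)
        dd = d_s - d_cal if s != calibrator_sample else 0.0
        se_dd = math.sqrt(se_s**2 + se_cal**2)
        rel = 2.0 ** (-dd)
        out[s] = DdctResult(
            sample=s,
            delta_ct_sample=d_s,
            delta_ct_calibrator=d_cal,
            ddct=dd,
            relative_expression=rel,
            percent_change=(rel - 1.0) * 100.0,
            replicate_se=rel * LOG2 * se_dd,
        )
    return out


def _delta_ct(mean_se, sample, target, reference):
    mt, set_ = mean_se(sample, target)
    mr, ser = mean_se(sample, reference)
    return mt - mr, math.sqrt(set_**2 + ser**2)


@dataclass(frozen=True)
class GroupComparison:
    test: str
    statistic: float
    p_value: float
    df: tuple
    posthoc: dict | None = None


def group_compare(values_by_group: dict[str, list], posthoc: bool = False) -> GroupComparison:
    """Two groups: pooled-variance Student t; more: one-way ANOVA.

    Textbook formulas, p-values from the corresponding scipy distribution.
    Optional Bonferroni-corrected pairwise t-tests for >2 groups.
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in values_by_group.items()}
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(g.size < 2 for g in groups.values()):
        raise ValueError("each group needs at least two values")
    arrays = list(groups.values())
    all_vals = np.concatenate(arrays)
    if np.allclose(all_vals, all_vals[0]):
        raise ValueError("degenerate variance: all values identical")

    if len(groups) == 2:
        a, b = arrays
        na, nb = a.size, b.size
        sp2 = (((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1))
               / (na + nb - 2))
        if sp2 == 0:
            raise ValueError("degenerate variance within both groups")
        t = (np.mean(a) - np.mean(b)) / math.sqrt(sp2 * (1 / na + 1 / nb))
        df = na + nb - 2
        p = 2.0 * float(stats.t.sf(abs(t), df))
        return GroupComparison("t", float(t), min(p, 1.0), (df,))

    k = len(groups)
    n = all_vals.size
    grand = np.mean(all_vals)
    ss_between = sum(g.size * (np.mean(g) - grand) ** 2 for g in arrays)
    ss_within = sum(np.sum((g - np.mean(g)) ** 2) for g in arrays)
    df_b, df_w = k - 1, n - k
    if ss_within == 0:
        raise ValueError("degenerate variance within groups")
    f = (ss_between / df_b) / (ss_within / df_w)
    p = float(stats.f.sf(f, df_b, df_w))
    ph = None
    if posthoc:
        names = list(groups)
        m = k * (k - 1) // 2
        ph = {}
        for i in range(k):
            for j in range(i + 1, k):
                sub = group_compare({names[i]: groups[names[i]],
                                     names[j]: groups[names[j]]})
                ph[f"{names[i]} vs {names[j]}"] = min(1.0, sub.p_value * m)
    return GroupComparison("anova", float(f), p, (df_b, df_w), ph)
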