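"""Copy-number verification from replicate qPCR ratios.

A locus genuinely residing in the host genome shows a target/standard
ratio near 1 (one copy per haploid genome, like the single-copy standard)
that is stable across samples and strains.  DNA from a contaminant or
symbiont fluctuates with titer, so its ratio varies strongly among
samples.  The informal published reading ("nearly constant across samples
and centered around 1") is formalised here as a conjunction:

    single_copy_genomic  iff  among-sample ANOVA p > alpha
                          and between-strain t-test p > alpha
                          and pooled mean inside [low, high]
                          and 1 inside mean +/- t_{0.975,n-1} * SE

``variable_titer`` is called when the among-sample variation is
significant or the mean falls outside the band; anything else is
indeterminate.  Tukey-Kramer pairwise comparisons (unequal-n studentized
range) accompany the ANOVA, as in the published analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class CopyNumberVerdict:
    locus: str
    mean_ratio: float
    se_ratio: float
    n: int
    anova_p: float
    strain_t_p: float
    call: str  # single_copy_genomic | variable_titer | indeterminate


@dataclass
class TukeyResult:
    f_stat: float
    p: float
    pairwise: pd.DataFrame  # group1, group2, meandiff, p_adj


def summarize_ratios(table: pd.DataFrame) -> pd.DataFrame:
    """Per-locus (and per-strain) mean and standard error of the ratio.

    Loci with a single replicate get SE = NaN and a flag.
    """
    _check_table(table)
    rows = []
    for (locus, strain), grp in table.groupby(["locus", "strain"], sort=True):
        r = grp["ratio"].to_numpy(dtype=float)
        rows.append({
            "locus": locus, "strain": strain, "n": len(r),
            "mean": float(np.mean(r)),
            "se": float(np.std(r, ddof=1) / np.sqrt(len(r))) if len(r) > 1 else np.nan,
            "single_replicate": len(r) < 2,
        })
    for locus, grp in table.groupby("locus", sort=True):
        r = grp["ratio"].to_numpy(dtype=float)
        rows.append({
            "locus": locus, "strain": "pooled", "n": len(r),
            "mean": float(np.mean(r)),
            "se": float(np.std(r, ddof=1) / np.sqrt(len(r))) if len(r) > 1 else np.nan,
            "single_replicate": len(r) < 2,
        })
    return pd.DataFrame(rows)


def anova_tukey(
    groups: dict[str, np.ndarray], alpha: float = 0.05,
    compute_pairwise: bool = True,
) -> TukeyResult:
    """One-way ANOVA plus Tukey-Kramer pairwise comparisons.

    Groups with fewer than 2 observations are excluded (with the exclusion
    visible in the pairwise table's absence).  Degenerate data with zero
    variance everywhere returns F=0, p=1 by convention.  The studentized
    range tail evaluation is comparatively expensive; callers that only
    need the omnibus F may pass ``compute_pairwise=False``.
    """
    usable = {k: np.asarray(v, dtype=float) for k, v in groups.items() if len(v) >= 2}
    if len(usable) < 2:
        raise ValueError("need at least two groups with >= 2 observations")
    names = sorted(usable)
    arrays = [usable[k] for k in names]
    pooled = np.concatenate(arrays)
    if np.allclose(pooled, pooled[0]):
        pairwise = pd.DataFrame(
            [(a, b, 0.0, 1.0) for ai, a in enumerate(names) for b in names[ai + 1:]],
            columns=["group1", "group2", "meandiff", "p_adj"])
        return TukeyResult(0.0, 1.0, pairwise)
    f_stat, p = stats.f_oneway(*arrays)
    if not compute_pairwise:
        return TukeyResult(float(f_stat), float(p),
                           pd.DataFrame(columns=["group1", "group2", "meandiff", "p_adj"]))
    # Tukey-Kramer: studentized range with unequal-n correction
    k = len(arrays)
    n_total = sum(len(a) for a in arrays)
    df_w = n_total - k
    ms_w = sum(((a - a.mean()) ** 2).sum() for a in arrays) / df_w
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            ni, nj = len(arrays[i]), len(arrays[j])
            diff = arrays[i].mean() - arrays[j].mean()
            se = np.sqrt(ms_w / 2 * (1 / ni + 1 / nj))
            q = abs(diff) / se if se > 0 else 0.0
            p_adj = float(stats.studentized_range.sf(q, k, df_w)) if se > 0 else 1.0
            rows.append((names[i], names[j], float(diff), min(1.0, p_adj)))
    pairwise = pd.DataFrame(rows, columns=["group1", "group2", "meandiff", "p_adj"])
    return TukeyResult(float(f_stat), float(p), pairwise)


def copy_number_call(
    table: pd.DataFrame,
    alpha: float = 0.05,
    band: tuple[float, float] = (0.5, 2.0),
) -> list[CopyNumberVerdict]:
    """Classify each locus as genomic single-copy, variable titer, or indeterminate.

    Among-sample variation is tested by one-way ANOVA over samples (a
    ``sample`` column groups technical replicates; without one, each row is
    its own sample and the ANOVA is skipped), the strain effect by a
    two-sample t-test on per-sample means, and the location by the band
    plus a confidence interval (over sample means) containing 1.

    ``alpha`` is the family-wise level of the whole call: the three
    stochastic components run at the Sidak-corrected level
    1-(1-alpha)^(1/3), so a genuinely genomic locus is mis-called at a
    rate close to ``alpha`` overall.
    """
    _check_table(table)
    has_samples = "sample" in table.columns
    a_comp = 1.0 - (1.0 - alpha) ** (1.0 / 3.0)
    verdicts = []
    for locus, grp in table.groupby("locus", sort=True):
        if has_samples:
            sample_groups = {
                key: g["ratio"].to_numpy(dtype=float)
                for key, g in grp.groupby(["strain", "sample"])
            }
        else:
            sample_groups = {
                (row.strain, i): np.array([row.ratio])
                for i, row in enumerate(grp.itertuples(index=False))
            }
        sample_means = {k: float(v.mean()) for k, v in sample_groups.items()}
        means = np.array(sorted(sample_means.values()))
        means = np.array([sample_means[k] for k in sorted(sample_means)])
        n = len(means)
        mean = float(means.mean())
        sd = float(np.std(means, ddof=1)) if n > 1 else 0.0
        se = sd / np.sqrt(n) if n > 1 else np.nan
        # among-sample ANOVA (needs technical replicates within samples)
        try:
            anova_p = anova_tukey(sample_groups, a_comp, compute_pairwise=False).p
        except ValueError:
            anova_p = np.nan
        # strain effect on per-sample means
        by_strain: dict[str, list[float]] = {}
        for (strain, _s), m in sample_means.items():
            by_strain.setdefault(strain, []).append(m)
        strains = sorted(by_strain)
        if len(strains) == 2 and all(len(by_strain[s]) >= 2 for s in strains):
            a, b = np.array(by_strain[strains[0]]), np.array(by_strain[strains[1]])
            if np.allclose(np.concatenate([a, b]), a[0]):
                t_p = 1.0
            else:
                t_p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
        else:
            t_p = np.nan
        if n > 1 and sd > 0:
            half = stats.t.ppf(1.0 - a_comp / 2.0, n - 1) * se
            ci_contains_1 = (mean - half) <= 1.0 <= (mean + half)
        else:
            ci_contains_1 = bool(np.isclose(mean, 1.0))
        in_band = band[0] <= mean <= band[1]
        anova_ok = (not np.isfinite(anova_p)) or anova_p > a_comp
        t_ok = (not np.isfinite(t_p)) or t_p > a_comp
        if anova_ok and t_ok and in_band and ci_contains_1:
            call = "single_copy_genomic"
        elif (np.isfinite(anova_p) and anova_p <= a_comp) or not in_band:
            call = "variable_titer"
        else:
            call = "indeterminate"
        verdicts.append(CopyNumberVerdict(
            locus, mean, float(se) if np.isfinite(se) else 0.0, n,
            float(anova_p) if np.isfinite(anova_p) else np.nan,
            float(t_p) if np.isfinite(t_p) else np.nan, call))
    return verdicts


def fold_change(
    expression: pd.DataFrame,
    reference_tissue: str = "whole_body",
) -> pd.DataFrame:
    """Per-tissue fold change of normalized copies versus a reference tissue.

    Expects columns (locus, tissue, replicate, copies); fold =
    mean(tissue)/mean(reference).  Tissue differences are flagged with the
    Tukey-adjusted p-value of the tissue-vs-reference comparison.
    """
    required = {"locus", "tissue", "replicate", "copies"}
    if not required.issubset(expression.columns):
        raise ValueError(f"expression table needs columns {sorted(required)}")
    rows = []
    for locus, grp in expression.groupby("locus", sort=True):
        tissues = {t: g["copies"].to_numpy(dtype=float) for t, g in grp.groupby("tissue")}
        if reference_tissue not in tissues:
            rows.append({"locus": locus, "tissue": reference_tissue,
                         "fold": np.nan, "p_adj": np.nan, "missing_reference": True})
            continue
        ref_mean = tissues[reference_tissue].mean()
        if ref_mean == 0:
            rows.append({"locus": locus, "tissue": reference_tissue,
                         "fold": np.nan, "p_adj": np.nan, "missing_reference": False})
            continue
        try:
            tk = anova_tukey(tissues)
            padj = {
                frozenset((a, b)): p for a, b, _, p in
                tk.pairwise.itertuples(index=False)
            }
        except ValueError:
            padj = {}
        for t, vals in sorted(tissues.items()):
            if t == reference_tissue:
                continue
            rows.append({
                "locus": locus, "tissue": t,
                "fold": float(vals.mean() / ref_mean),
                "p_adj": float(padj.get(frozenset((t, reference_tissue)), np.nan)),
                "missing_reference": False,
            })
    return pd.DataFrame(rows)


def _check_table(table: pd.DataFrame) -> None:
    required = {"locus", "strain", "replicate", "ratio"}
    if not required.issubset(table.columns):
        raise ValueError(f"qPCR table needs columns {sorted(required)}")
    if (table["ratio"] <= 0).any():
        raise ValueError("ratios must be positive")
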