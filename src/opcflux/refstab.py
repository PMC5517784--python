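"""Reference-gene stability ranking: geNorm, NormFinder, ANOVA screen.

Candidate housekeeping genes are ranked by two complementary criteria, both
computed on log2 expression:

* **geNorm** — for each candidate j, the average over the other candidates k
  of V_jk, the sample standard deviation (n-1 denominator) of
  ``log2(x_j / x_k)`` across samples. A gene whose expression tracks the
  others proportionally has a low average pairwise variation M; stepwise
  exclusion of the worst gene yields the ranking, with the final pair tied
  at rank 1 (the pairwise measure cannot separate two genes).

* **NormFinder** (model-based, Andersen et al. 2004) — a variance
  decomposition of log2 expression into intragroup (within-condition) noise
  and intergroup (condition-dependent) shifts, with empirical-Bayes
  shrinkage of the per-group differences; the stability value averages the
  absolute shrunken intergroup difference plus its standard error over
  groups. Lower is more stable in both methods.

An ANOVA screen flags candidates whose log2 expression differs
significantly between conditions.

Tie-breaks are lexicographic on gene id throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .matrix import ExpressionMatrix

__all__ = [
    "genorm_m_values",
    "genorm_rank",
    "normfinder_stability",
    "anova_screen",
    "stability_table",
]


def _log2_candidates(matrix: ExpressionMatrix, candidates) -> pd.DataFrame:
    sub = matrix.restrict(list(candidates))
    return np.log2(sub.data)


def genorm_m_values(matrix: ExpressionMatrix, candidates=None) -> pd.Series:
    """geNorm average expression stability M per candidate gene.

    ``candidates`` defaults to every row of the matrix. Needs at least two
    candidates and two samples. M is invariant to per-sample scaling
    because within-sample ratios cancel any common factor.
    """
    candidates = matrix.feature_ids if candidates is None else list(candidates)
    if len(candidates) < 2:
        raise ValueError("geNorm needs at least 2 candidate genes")
    if len(matrix.sample_ids) < 2:
        raise ValueError("geNorm needs at least 2 samples")
    logs = _log2_candidates(matrix, candidates).to_numpy()
    # V[j, k] = SD over samples of log2 ratio of genes j and k
    diff = logs[:, None, :] - logs[None, :, :]
    v = diff.std(axis=2, ddof=1)
    n = len(candidates)
    m = v.sum(axis=1) / (n - 1)  # diagonal is zero
    return pd.Series(m, index=candidates, name="genorm_M")


def genorm_rank(matrix: ExpressionMatrix, candidates=None) -> pd.DataFrame:
    """Stepwise geNorm ranking with the published exclusion scheme.

    Iteratively recomputes M on the surviving set and excludes the gene with
    the largest M until two genes remain; the final two share rank 1. The
    reported M for each gene is its value in the set it was excluded from
    (for the final pair, their common M in the two-gene set). Ties in the
    exclusion choice are broken by excluding the lexicographically greater
    gene id.

    Returns a DataFrame indexed by gene with columns ``genorm_M`` and
    ``genorm_rank``.
    """
    candidates = matrix.feature_ids if candidates is None else list(candidates)
    if len(candidates) < 3:
        raise ValueError("geNorm ranking needs at least 3 candidate genes")
    surviving = sorted(candidates)
    records: list[tuple[str, float, int]] = []
    rank = len(surviving) - 1
    while len(surviving) > 2:
        m = genorm_m_values(matrix, surviving)
        worst_m = m.max()
        worst = max(g for g in surviving if m[g] == worst_m)
        records.append((worst, float(m[worst]), rank))
        surviving.remove(worst)
        rank -= 1
    m = genorm_m_values(matrix, surviving)
    for g in sorted(surviving):
        records.append((g, float(m[g]), 1))
    out = pd.DataFrame(
        records, columns=["gene", "genorm_M", "genorm_rank"]
    ).set_index("gene")
    return out.loc[sorted(candidates)]


def normfinder_stability(
    matrix: ExpressionMatrix, candidates=None
) -> pd.Series:
    """NormFinder model-based stability value per candidate gene.

    Implements the variance decomposition on log2 data: per-sample centering
    over the candidate panel (removes array effects), per-gene/per-group
    means and intragroup variances with the small-panel bias correction
    ``I/(I-2)``, intergroup differences d (group deviation of the gene
    corrected by the panel average), empirical-Bayes shrinkage of d toward 0
    by the ratio of the estimated true intergroup variance to its total
    variance, and finally

        stability(gene) = mean over groups of |d_shrunken| + SE(d)

    where ``SE(d) = sqrt(sigma2_intra / n_group)``. Lower = more stable.
    Requires at least 3 candidates and at least 2 groups of >= 2 samples.
    """
    candidates = matrix.feature_ids if candidates is None else list(candidates)
    n_genes = len(candidates)
    if n_genes < 3:
        raise ValueError("NormFinder needs at least 3 candidate genes")
    groups = matrix.conditions
    n_groups = len(groups)
    if n_groups < 2:
        raise ValueError("NormFinder needs at least 2 condition groups")
    logs = _log2_candidates(matrix, candidates)
    centered = logs - logs.mean(axis=0)

    a = np.empty((n_genes, n_groups))  # per-gene, per-group means
    s2 = np.empty((n_genes, n_groups))  # raw intragroup variances
    n_per = np.empty(n_groups)
    for j, grp in enumerate(groups):
        cols = matrix.samples_of(grp)
        if len(cols) < 2:
            raise ValueError(f"condition {grp!r} has fewer than 2 samples")
        block = centered[cols].to_numpy()
        n_per[j] = len(cols)
        a[:, j] = block.mean(axis=1)
        s2[:, j] = block.var(axis=1, ddof=1)

    # bias-corrected intragroup variances (sample centering over I genes
    # contaminates each residual with the panel average)
    sigma2 = (s2 - s2.sum(axis=0) / (n_genes * (n_genes - 1))) * (
        n_genes / (n_genes - 2)
    )
    sigma2 = np.clip(sigma2, 0.0, None)

    d = a - a.mean(axis=1, keepdims=True)  # intergroup differences
    c = sigma2 / n_per  # sampling variance of d-hat (per gene, group)

    df = (n_genes - 1) * (n_groups - 1)
    gamma2 = max(float(d.ravel() @ d.ravel()) / df - float(c.mean()), 0.0)
    if gamma2 > 0:
        d_shrunk = d * gamma2 / (gamma2 + c)
    else:
        d_shrunk = np.zeros_like(d)
    rho = (np.abs(d_shrunk) + np.sqrt(c)).mean(axis=1)
    return pd.Series(rho, index=candidates, name="normfinder_value")


def anova_screen(matrix: ExpressionMatrix, candidates=None) -> pd.Series:
    """One-way ANOVA p-value per candidate on log2 values across conditions.

    Genes with p < 0.05 are conventionally flagged as significantly
    variable (hence poor reference candidates).
    """
    candidates = matrix.feature_ids if candidates is None else list(candidates)
    logs = _log2_candidates(matrix, candidates)
    blocks = []
    for grp in matrix.conditions:
        cols = matrix.samples_of(grp)
        if len(cols) < 2:
            raise ValueError(f"condition {grp!r} has fewer than 2 samples")
        blocks.append(logs[cols].to_numpy())
    if len(blocks) < 2:
        raise ValueError("ANOVA screen needs at least 2 condition groups")
    result = scipy.stats.f_oneway(*blocks, axis=1)
    return pd.Series(np.atleast_1d(result.pvalue), index=candidates, name="anova_p")


def _rank_low_first(values: pd.Series) -> pd.Series:
    """Dense ranks, 1 = lowest value; equal values share a rank."""
    return values.rank(method="dense").astype(int)


def stability_table(matrix: ExpressionMatrix, candidates) -> pd.DataFrame:
    """Combined stability report: geNorm, NormFinder and ANOVA per candidate.

    Columns: ``genorm_M``, ``genorm_rank`` (stepwise ranking, final pair
    tied at 1), ``normfinder_value``, ``normfinder_rank`` (dense rank of
    the value), ``anova_p``.
    """
    gn = genorm_rank(matrix, candidates)
    nf = normfinder_stability(matrix, candidates)
    table = gn.copy()
    table["normfinder_value"] = nf
    table["normfinder_rank"] = _rank_low_first(nf.round(12))
    table["anova_p"] = anova_screen(matrix, candidates)
    return table
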