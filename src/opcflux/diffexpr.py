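"""Reference-gene normalization, fold changes, and differential-expression
calls (one-way ANOVA + Tukey HSD + Benjamini–Hochberg FDR).

Workflow: divide every gene by the per-sample geometric mean of the chosen
reference genes (removing any per-sample multiplicative artifact exactly),
express each gene in each condition as the ratio r of mean normalized
expression to the control mean, test on log2 normalized values with one-way
ANOVA and Tukey's studentized-range post hoc comparisons against control,
correct across all gene x condition tests with BH-FDR, and call a gene
down (up) in a condition when r <= 1/2 (>= 2), Tukey p < 0.01 and FDR
q < 0.1 (cutoffs configurable, fold-change boundary inclusive).

An optional empirical-Bayes variance-moderation branch shrinks the per-gene
residual variances toward a moment-matched prior before the Tukey step.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.special
import scipy.stats
from scipy.interpolate import PchipInterpolator
from statsmodels.stats.multitest import multipletests

from .matrix import ExpressionMatrix

__all__ = [
    "normalize_to_references",
    "fold_change",
    "anova_tukey",
    "bh_fdr",
    "estimate_variance_prior",
    "moderate_variance",
    "call_de",
    "de_pipeline",
]


def normalize_to_references(
    matrix: ExpressionMatrix, reference_genes
) -> ExpressionMatrix:
    """Divide each sample by the geometric mean of its reference-gene values."""
    reference_genes = list(reference_genes)
    if not reference_genes:
        raise ValueError("need at least one reference gene")
    missing = [g for g in reference_genes if g not in matrix.data.index]
    if missing:
        raise KeyError(f"reference genes not in matrix: {missing}")
    ref = matrix.data.loc[reference_genes].to_numpy()
    factors = np.exp(np.mean(np.log(ref), axis=0))  # per sample
    return matrix.copy_with(matrix.data / factors)


def fold_change(matrix: ExpressionMatrix, control: str | None = None) -> pd.DataFrame:
    """Relative expression r per gene and non-control condition.

    r(g, c) = mean over c's replicates / mean over control replicates of the
    (normalized) values. Returns a tidy DataFrame with columns ``gene``,
    ``condition``, ``r``, ``log2fc`` and ``percent_down`` ((1 - r) * 100
    where r < 1, else NaN).
    """
    control = matrix.conditions[0] if control is None else control
    if control not in matrix.conditions:
        raise ValueError(f"control condition {control!r} not in design")
    ctrl_mean = matrix.data[matrix.samples_of(control)].mean(axis=1)
    records = []
    for cond in matrix.conditions:
        if cond == control:
            continue
        r = matrix.data[matrix.samples_of(cond)].mean(axis=1) / ctrl_mean
        for gene, val in r.items():
            records.append(
                (
                    gene,
                    cond,
                    float(val),
                    float(np.log2(val)),
                    float((1.0 - val) * 100.0) if val < 1.0 else np.nan,
                )
            )
    return pd.DataFrame(
        records, columns=["gene", "condition", "r", "log2fc", "percent_down"]
    )


# -- Tukey HSD p-values ----------------------------------------------------
#
# scipy's studentized-range distribution is accurate but slow (~10 ms per
# point). For whole-matrix calls the survival function is evaluated through
# a cached monotone (PCHIP) interpolant of log sf over a q-grid per
# (n_groups, df); the absolute error against the direct computation is
# below 1e-6 over the grid, far inside the decision tolerances used here.

_TUKEY_GRID_MAX = 25.0
_tukey_cache: dict[tuple[int, int], PchipInterpolator] = {}


def _tukey_sf(q: np.ndarray, n_groups: int, df: float) -> np.ndarray:
    key = (int(n_groups), int(round(df)))
    interp = _tukey_cache.get(key)
    if interp is None:
        grid = np.concatenate(
            [np.linspace(0.0, 4.0, 81), np.linspace(4.05, _TUKEY_GRID_MAX, 120)]
        )
        sf = scipy.stats.studentized_range.sf(grid, n_groups, df)
        logsf = np.log(np.clip(sf, 1e-300, None))
        interp = PchipInterpolator(grid, logsf, extrapolate=True)
        _tukey_cache[key] = interp
    q = np.clip(np.asarray(q, dtype=float), 0.0, _TUKEY_GRID_MAX)
    return np.exp(interp(q))


def anova_tukey(
    matrix: ExpressionMatrix,
    control: str | None = None,
    moderate: bool = False,
) -> pd.DataFrame:
    """Per-gene omnibus ANOVA and Tukey HSD contrasts against control.

    The one-way ANOVA is computed on log2 (normalized) values over all
    conditions; each non-control condition is then compared with control by
    the Tukey–Kramer studentized-range statistic sharing the pooled
    within-group variance. With ``moderate=True`` the pooled variances are
    first shrunk toward a moment-matched prior (empirical Bayes) and the
    residual degrees of freedom augmented accordingly.

    Returns a tidy DataFrame: ``gene``, ``condition``, ``anova_p``, ``p``
    (the Tukey p for that contrast).
    """
    control = matrix.conditions[0] if control is None else control
    conditions = matrix.conditions
    if control not in conditions:
        raise ValueError(f"control condition {control!r} not in design")
    logs = np.log2(matrix.data.to_numpy())
    group_cols = {c: [matrix.sample_ids.index(s) for s in matrix.samples_of(c)] for c in conditions}
    for c, cols in group_cols.items():
        if len(cols) < 2:
            raise ValueError(f"condition {c!r} has fewer than 2 replicates")
    k = len(conditions)
    n_total = logs.shape[1]
    df_within = n_total - k

    means = {c: logs[:, cols].mean(axis=1) for c, cols in group_cols.items()}
    ssw = sum(
        ((logs[:, cols] - means[c][:, None]) ** 2).sum(axis=1)
        for c, cols in group_cols.items()
    )
    msw = ssw / df_within
    grand = logs.mean(axis=1)
    ssb = sum(
        len(cols) * (means[c] - grand) ** 2 for c, cols in group_cols.items()
    )
    msb = ssb / (k - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(msw > 0, msb / np.where(msw > 0, msw, 1.0), np.inf)
        f = np.where((msw == 0) & (msb == 0), 0.0, f)
    anova_p = scipy.stats.f.sf(f, k - 1, df_within)

    df_tukey = df_within
    if moderate:
        if int((msw > 0).sum()) >= 2:
            d0, s0sq = estimate_variance_prior(msw, df_within)
            msw = moderate_variance(msw, df_within, d0, s0sq)
            df_tukey = df_within + (int(d0) if np.isfinite(d0) else 10**6)
        # with (near-)degenerate variances there is nothing to moderate

    n_ctrl = len(group_cols[control])
    records = []
    for cond in conditions:
        if cond == control:
            continue
        n_c = len(group_cols[cond])
        se = np.sqrt(msw / 2.0 * (1.0 / n_c + 1.0 / n_ctrl))
        with np.errstate(divide="ignore", invalid="ignore"):
            q = np.where(
                se > 0,
                np.abs(means[cond] - means[control]) / np.where(se > 0, se, 1.0),
                np.where(means[cond] == means[control], 0.0, np.inf),
            )
        p = _tukey_sf(q, k, df_tukey)
        for gene, ap, pv in zip(matrix.feature_ids, anova_p, p):
            records.append((gene, cond, float(ap), float(pv)))
    return pd.DataFrame(records, columns=["gene", "condition", "anova_p", "p"])


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted values (order-preserving)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def estimate_variance_prior(s2, df) -> tuple[float, float]:
    """Moment-match an inverse-chi-square prior (d0, s0^2) to observed variances.

    Matches the first two moments of log s^2 (digamma/trigamma relations of
    the scaled-F sampling model), the standard empirical-Bayes recipe for
    variance shrinkage. Returns ``(inf, geometric-style mean)`` when the
    observed spread is no larger than sampling noise alone.
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[np.isfinite(s2) & (s2 > 0)]
    if s2.size < 2:
        raise ValueError("need at least 2 positive variances to fit a prior")
    df = float(df)
    z = np.log(s2)
    e = z - scipy.special.digamma(df / 2.0) + np.log(df / 2.0)
    excess = z.var(ddof=1) - float(scipy.special.polygamma(1, df / 2.0))
    if excess <= 0:
        return np.inf, float(np.exp(e.mean()))
    # invert trigamma by Newton iteration
    x = 0.5 + 1.0 / excess
    for _ in range(50):
        tri = float(scipy.special.polygamma(1, x))
        delta = tri * (1.0 - tri / excess) / float(scipy.special.polygamma(2, x))
        x += delta
        if abs(delta) < 1e-10 * x:
            break
    d0 = 2.0 * x
    s0sq = float(np.exp(e.mean() + scipy.special.digamma(x) - np.log(x)))
    return d0, s0sq


def moderate_variance(s2, df, prior_df: float, prior_var: float):
    """Shrink variances toward the prior: (d0*s0^2 + df*s^2) / (d0 + df)."""
    s2 = np.asarray(s2, dtype=float)
    if np.any(s2 < 0):
        raise ValueError("variances must be non-negative")
    df = float(df)
    if df < 1:
        raise ValueError("residual df must be >= 1")
    if prior_df < 0:
        raise ValueError("prior df must be >= 0")
    if prior_df + df == 0:
        raise ValueError("prior df + residual df must be positive")
    if np.isinf(prior_df):
        return np.full_like(s2, prior_var)
    return (prior_df * prior_var + df * s2) / (prior_df + df)


def call_de(
    fc: pd.DataFrame,
    stats: pd.DataFrame,
    fc_cutoff: float = 2.0,
    p_cutoff: float = 0.01,
    fdr_cutoff: float = 0.1,
) -> pd.DataFrame:
    """Combine fold changes and test statistics into up/down/none calls.

    ``fc`` and ``stats`` must cover identical (gene, condition) cells. FDR
    q-values are computed across all Tukey p-values in ``stats``. A call is
    ``down`` iff r <= 1/fc_cutoff, p < p_cutoff and q < fdr_cutoff
    (boundary r inclusive); ``up`` symmetrically with r >= fc_cutoff.
    """
    if fc_cutoff < 1:
        raise ValueError("fc_cutoff must be >= 1")
    merged = fc.merge(stats, on=["gene", "condition"], how="outer", indicator=True)
    if (merged["_merge"] != "both").any():
        bad = merged.loc[merged["_merge"] != "both", ["gene", "condition"]]
        raise ValueError(
            f"fold-change and statistics tables are misaligned on cells:\n{bad}"
        )
    merged = merged.drop(columns="_merge")
    if "q" not in merged.columns:
        merged["q"] = bh_fdr(merged["p"].to_numpy())
    sig = (merged["p"] < p_cutoff) & (merged["q"] < fdr_cutoff)
    call = np.where(
        sig & (merged["r"] <= 1.0 / fc_cutoff),
        "down",
        np.where(sig & (merged["r"] >= fc_cutoff), "up", "none"),
    )
    merged["call"] = call
    cols = ["gene", "condition", "r", "log2fc", "percent_down"]
    if "anova_p" in merged.columns:
        cols.append("anova_p")
    return merged[cols + ["p", "q", "call"]]


def de_pipeline(
    matrix: ExpressionMatrix,
    reference_genes,
    control: str | None = None,
    fc_cutoff: float = 2.0,
    p_cutoff: float = 0.01,
    fdr_cutoff: float = 0.1,
    moderate: bool = False,
) -> pd.DataFrame:
    """Reference-normalize, compute fold changes and statistics, and call DE."""
    norm = normalize_to_references(matrix, reference_genes)
    fc = fold_change(norm, control=control)
    stats = anova_tukey(norm, control=control, moderate=moderate)
    return call_de(
        fc,
        stats,
        fc_cutoff=fc_cutoff,
        p_cutoff=p_cutoff,
        fdr_cutoff=fdr_cutoff,
    )
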