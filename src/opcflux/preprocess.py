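"""Array-level preprocessing: percentile normalization, low-expression
filtering, probe-to-gene merging.

The three steps mirror the standard one-color microarray workflow the
analysis assumes: per-sample 75th-percentile scaling for inter-array
comparability, removal of features whose typical intensity falls below the
30% quantile of the pooled signal distribution, and collapsing multiple
probes of a gene into one gene-level value by geometric mean (consistent
with the multiplicative error model).

Percentile definition: linear interpolation between order statistics
(``numpy.quantile`` default), fixed here for bit-stability.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix, FormatError

__all__ = [
    "percentile_normalize",
    "low_expression_filter",
    "merge_probes",
    "read_probe_map",
    "write_probe_map",
]


def percentile_normalize(
    matrix: ExpressionMatrix, percentile: float = 75.0
) -> ExpressionMatrix:
    """Scale each sample so its given percentile hits a common target.

    The target is the geometric mean of the per-sample percentiles, which
    keeps the overall intensity scale of the experiment; any common target
    yields identical downstream ratios. Idempotent: a second application is
    a no-op (each sample's percentile already equals the target).
    """
    if not 0.0 < percentile < 100.0:
        raise ValueError(f"percentile must be in (0, 100), got {percentile}")
    values = matrix.data.to_numpy()
    per_sample = np.quantile(values, percentile / 100.0, axis=0)
    if np.any(per_sample <= 0):
        j = int(np.argmax(per_sample <= 0))
        raise ValueError(
            f"sample {matrix.sample_ids[j]!r} has non-positive "
            f"{percentile}th percentile"
        )
    target = float(np.exp(np.mean(np.log(per_sample))))
    scaled = values * (target / per_sample)
    return matrix.copy_with(
        pd.DataFrame(scaled, index=matrix.data.index, columns=matrix.data.columns)
    )


def low_expression_filter(
    matrix: ExpressionMatrix, quantile: float = 0.30
) -> tuple[ExpressionMatrix, list[str]]:
    """Drop rows whose median across samples falls below the pooled quantile.

    The threshold is the given quantile of the pooled value distribution
    over the whole matrix (all rows and samples); the per-row summary
    compared against it is the median across samples (robust to a few
    outlying arrays). Returns the kept matrix and the removed row ids.
    """
    if not 0.0 < quantile < 1.0:
        raise ValueError(f"quantile must be in (0, 1), got {quantile}")
    values = matrix.data.to_numpy()
    threshold = float(np.quantile(values, quantile))
    medians = np.median(values, axis=1)
    keep = medians >= threshold
    if not keep.any():
        raise ValueError("low-expression filter would remove every row")
    removed = [rid for rid, k in zip(matrix.feature_ids, keep) if not k]
    return matrix.copy_with(matrix.data.loc[keep]), removed


def merge_probes(
    matrix: ExpressionMatrix, probe_map: dict[str, str]
) -> ExpressionMatrix:
    """Collapse probe rows to gene rows by per-sample geometric mean.

    Every row id must be present in ``probe_map`` (probe → gene, many-to-one).
    Output rows are keyed by gene id, in lexicographic order for
    determinism. Geometric averaging commutes with per-sample rescaling.
    """
    unmapped = [p for p in matrix.feature_ids if p not in probe_map]
    if unmapped:
        raise KeyError(f"probes missing from probe map: {unmapped}")
    genes = pd.Index([probe_map[p] for p in matrix.feature_ids], name="id")
    logs = np.log(matrix.data.to_numpy())
    merged = (
        pd.DataFrame(logs, index=genes, columns=matrix.data.columns)
        .groupby(level=0, sort=True)
        .mean()
    )
    return matrix.copy_with(np.exp(merged))


def write_probe_map(path, probe_map: dict[str, str]) -> None:
    pd.Series(probe_map, name="gene_id").rename_axis("probe_id").to_csv(path, sep="\t")


def read_probe_map(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["probe_id", "gene_id"]:
        raise FormatError(
            f"probe map {path} must have header 'probe_id<TAB>gene_id', "
            f"got {df.columns.tolist()}"
        )
    if df["probe_id"].duplicated().any():
        dupes = df["probe_id"][df["probe_id"].duplicated()].tolist()
        raise FormatError(f"probe mapped to multiple genes: {dupes}")
    return dict(zip(df["probe_id"], df["gene_id"]))
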