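"""Expression matrix container and TSV round-trip I/O.

The whole pipeline works on positive intensity values (one-color microarray
scale, arbitrary units) held in a :class:`ExpressionMatrix`: a pandas
DataFrame of features (probes or genes) by samples, plus a sample → condition
design map. Values must be strictly positive and finite so that every
downstream ratio and log transform is defined.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "FormatError",
    "read_expression",
    "write_expression",
    "read_design",
    "write_design",
]


class FormatError(ValueError):
    """Malformed expression/design input (names the offending row/column)."""


@dataclass
class ExpressionMatrix:
    """Feature-by-sample positive intensity matrix with a condition design.

    Parameters
    ----------
    data:
        DataFrame, rows indexed by unique feature ids (probe or gene symbols),
        columns by unique sample ids; strictly positive finite floats.
    design:
        Series mapping sample id → condition label, indexed exactly by the
        matrix columns (order-insensitive).
    """

    data: pd.DataFrame
    design: pd.Series

    def __post_init__(self) -> None:
        self.data = self.data.astype(float)
        self.design = self.design.astype(str)
        self.validate()

    def validate(self) -> None:
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate feature ids: {dupes}")
        if self.data.columns.has_duplicates:
            dupes = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids: {dupes}")
        vals = self.data.to_numpy()
        bad = ~np.isfinite(vals) | (vals <= 0)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise FormatError(
                "non-positive or non-finite intensity at "
                f"row {self.data.index[i]!r}, sample {self.data.columns[j]!r}"
            )
        missing = set(self.data.columns) - set(self.design.index)
        if missing:
            raise FormatError(f"samples missing from design: {sorted(missing)}")
        # align design to column order, dropping unused entries
        self.design = self.design.reindex(self.data.columns)

    # -- convenience -------------------------------------------------------

    @property
    def feature_ids(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.data.columns.tolist()

    @property
    def conditions(self) -> list[str]:
        """Condition labels in first-appearance (design) order."""
        seen: dict[str, None] = {}
        for c in self.design:
            seen.setdefault(c, None)
        return list(seen)

    def samples_of(self, condition: str) -> list[str]:
        return self.design.index[self.design == condition].tolist()

    def restrict(self, feature_ids) -> "ExpressionMatrix":
        """Sub-matrix for the given features (error on absentees)."""
        missing = [g for g in feature_ids if g not in self.data.index]
        if missing:
            raise KeyError(f"features not in matrix: {missing}")
        return ExpressionMatrix(self.data.loc[list(feature_ids)], self.design.copy())

    def copy_with(self, data: pd.DataFrame) -> "ExpressionMatrix":
        return ExpressionMatrix(data, self.design.copy())

    def equals(self, other: "ExpressionMatrix", rtol: float = 0.0) -> bool:
        if self.feature_ids != other.feature_ids or self.sample_ids != other.sample_ids:
            return False
        if not self.design.equals(other.design):
            return False
        if rtol == 0.0:
            return bool(np.array_equal(self.data.to_numpy(), other.data.to_numpy()))
        return bool(
            np.allclose(self.data.to_numpy(), other.data.to_numpy(), rtol=rtol, atol=0.0)
        )


# -- TSV I/O ---------------------------------------------------------------
#
# Expression TSV: header `id<TAB>sample1<TAB>...`; design TSV:
# `sample<TAB>condition`. Values written with 12 significant digits.


def write_expression(path, matrix: ExpressionMatrix, design_path=None) -> None:
    """Write expression TSV (and, if given, the companion design TSV)."""
    df = matrix.data.copy()
    df.index.name = "id"
    df.to_csv(path, sep="\t", float_format="%.12g")
    if design_path is not None:
        write_design(design_path, matrix.design)


def write_design(path, design: pd.Series) -> None:
    out = design.rename("condition").to_frame()
    out.index.name = "sample"
    out.to_csv(path, sep="\t")


def read_design(path) -> pd.Series:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"cannot parse design TSV {path}: {exc}") from exc
    if list(df.columns[:2]) != ["sample", "condition"]:
        raise FormatError(
            f"design TSV {path} must have header 'sample<TAB>condition', "
            f"got {df.columns.tolist()}"
        )
    if df["sample"].duplicated().any():
        dupes = df["sample"][df["sample"].duplicated()].tolist()
        raise FormatError(f"duplicated sample id in design: {dupes}")
    return df.set_index("sample")["condition"]


def read_expression(path, design_path) -> ExpressionMatrix:
    """Read expression + design TSVs, enforcing the container invariants."""
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:
        raise FormatError(f"cannot parse expression TSV {path}: {exc}") from exc
    if df.columns.duplicated().any():
        dupes = df.columns[df.columns.duplicated()].unique().tolist()
        raise FormatError(f"duplicated sample id in {path}: {dupes}")
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"duplicated feature id in {path}: {dupes}")
    design = read_design(design_path)
    return ExpressionMatrix(df, design)
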