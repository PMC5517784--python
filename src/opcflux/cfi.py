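"""Cumulative Flux Index: multiplicative pathway impairment scoring.

The CFI condenses the differential expression of a metabolic pathway's
enzymes in one condition into a single factor: the product, over pathway
members called significantly changed, of their relative expression r versus
control. Genes with no significant change contribute a neutral factor 1;
up-regulated members contribute their r > 1. The total CFI of a condition
is the product of its pathway CFIs (glycolysis x TCA cycle x electron
transport chain). Under a multiplicative view of flux control — each
enzyme's activity scales the attainable flux through its step — a lower
CFI means a stronger inferred bioenergetic impairment, and conditions are
ranked by ascending total CFI.

The multiplicative rule is deliberately isolated behind this module's
interface so alternative aggregations can be swapped in.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = [
    "PathwaySet",
    "CfiResult",
    "GENE_ALIASES",
    "resolve_gene",
    "default_pathways",
    "read_gmt",
    "write_gmt",
    "pathway_cfi",
    "total_cfi",
    "cfi_results",
    "rank_conditions",
    "format_total",
]

#: Reconciliation of shorthand enzyme names (as used in summary tables)
#: with the gene symbols used on the arrays and in the figures.
GENE_ALIASES = {
    "Eno": "Eno1",
    "Pdh": "Pdha1",
    "Sdhaf2": "Sdh",
    "Pgam": "Pgam1",
    "Hk1": "Hk",
    "Atp5a": "Atp5a1",
}


def resolve_gene(name: str) -> str:
    """Map a shorthand enzyme name onto its array gene symbol."""
    return GENE_ALIASES.get(name, name)


@dataclass(frozen=True)
class PathwaySet:
    """A named gene set (glycolysis, tca, etc; extensible)."""

    name: str
    genes: tuple[str, ...]
    description: str = ""

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"pathway {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"pathway {self.name!r} has duplicate gene ids")


@dataclass(frozen=True)
class CfiResult:
    """Per-condition CFI summary."""

    condition: str
    pathway_cfi: dict[str, float]
    total: float
    n_down: dict[str, int]
    n_up: dict[str, int]


def default_pathways() -> list[PathwaySet]:
    """The bundled glucose-metabolism panels."""
    from .simulate import PATHWAY_GENES

    descriptions = {
        "glycolysis": "glycolytic pathway enzymes",
        "tca": "tricarboxylic acid cycle enzymes",
        "etc": "electron transport chain / ATP synthesis",
    }
    return [
        PathwaySet(name, tuple(genes), descriptions.get(name, ""))
        for name, genes in PATHWAY_GENES.items()
    ]


def read_gmt(path) -> list[PathwaySet]:
    """Read gene sets from GMT (set name, description, member genes)."""
    sets = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs name, description and "
                    "at least one gene"
                )
            sets.append(PathwaySet(parts[0], tuple(parts[2:]), parts[1]))
    return sets


def write_gmt(path, pathways) -> None:
    with open(path, "w") as fh:
        for ps in pathways:
            fh.write("\t".join([ps.name, ps.description, *ps.genes]) + "\n")


def pathway_cfi(
    calls: pd.DataFrame, pathway: PathwaySet, condition: str
) -> float:
    """Product of r over the pathway's significantly changed members.

    ``calls`` is the DE call table (columns gene, condition, r, call).
    Every pathway member must be present for the condition; an absent
    member (for example filtered out upstream) is an error rather than a
    silent neutral factor.
    """
    sub = calls[calls["condition"] == condition].set_index("gene")
    missing = [g for g in pathway.genes if g not in sub.index]
    if missing:
        raise KeyError(
            f"pathway {pathway.name!r} members absent from calls for "
            f"{condition!r}: {missing}"
        )
    member = sub.loc[list(pathway.genes)]
    changed = member[member["call"] != "none"]
    value = float(changed["r"].prod())  # empty product -> 1.0
    if not value > 0:
        raise ValueError(
            f"non-positive relative expression in pathway {pathway.name!r}"
        )
    return value


def total_cfi(pathway_cfis) -> float:
    """Product of the per-pathway CFI values."""
    values = list(
        pathway_cfis.values() if isinstance(pathway_cfis, dict) else pathway_cfis
    )
    if not values:
        raise ValueError("need at least one pathway CFI")
    total = 1.0
    for v in values:
        if not v > 0:
            raise ValueError(f"pathway CFI must be positive, got {v}")
        total *= float(v)
    return total


def cfi_results(
    calls: pd.DataFrame, pathways, conditions=None
) -> list[CfiResult]:
    """Compute per-condition pathway CFIs, totals and change counts."""
    if conditions is None:
        conditions = list(dict.fromkeys(calls["condition"]))
    results = []
    for cond in conditions:
        per_pathway: dict[str, float] = {}
        n_down: dict[str, int] = {}
        n_up: dict[str, int] = {}
        sub = calls[calls["condition"] == cond].set_index("gene")
        for ps in pathways:
            per_pathway[ps.name] = pathway_cfi(calls, ps, cond)
            member = sub.loc[[g for g in ps.genes]]
            n_down[ps.name] = int((member["call"] == "down").sum())
            n_up[ps.name] = int((member["call"] == "up").sum())
        results.append(
            CfiResult(cond, per_pathway, total_cfi(per_pathway), n_down, n_up)
        )
    return results


def rank_conditions(results) -> list[CfiResult]:
    """Ascending total CFI (lower = stronger inferred impairment).

    Ties are broken lexicographically on the condition label.
    """
    if len(results) < 1:
        raise ValueError("need at least one condition")
    return sorted(results, key=lambda r: (r.total, r.condition))


def format_total(value: float) -> str:
    """Scientific notation at 2 significant figures, e.g. ``1.9E-07``."""
    return f"{value:.1E}"
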