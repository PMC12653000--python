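"""Cross-species ortholog integration.

Ortholog links carry an integer database-support score (a count of ortholog
prediction databases agreeing on the pair, DIOPT-style, 1-15); the analysis
keeps pairs supported by at least 12 by default.  On top of the filtered
links: joined per-gene cross-species tables, Venn overlaps of genes owning
highly enriched transcripts, and disease-association summaries.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from tisspec.io_formats import ExpressionMatrix, PairTable
from tisspec.specificity import SpecificityMatrix, _require_normalized

logger = logging.getLogger(__name__)


def round_half_up(value: float, decimals: int = 1) -> float:
    """Decimal half-up rounding (118/318 -> 37.1), matching printed tables."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class VennResult:
    """Exact region decomposition of 2 or 3 named sets."""

    set_names: list[str]
    regions: dict[frozenset, set]  # key = subset of set names the region belongs to

    def count(self, *names: str) -> int:
        return len(self.regions.get(frozenset(names), set()))

    @property
    def union_size(self) -> int:
        return sum(len(v) for v in self.regions.values())

    def percent_of(self, region_names: tuple, relative_to: str) -> float:
        """Region size as a percentage of one named set's size."""
        set_size = sum(
            len(m) for key, m in self.regions.items() if relative_to in key
        )
        if set_size == 0:
            return 0.0
        return round_half_up(100 * len(self.regions[frozenset(region_names)]) / set_size, 2)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"region": "&".join(sorted(k)), "count": len(v), "members": ";".join(sorted(v))}
            for k, v in sorted(self.regions.items(), key=lambda kv: sorted(kv[0]))
        ]
        return pd.DataFrame(rows)


@dataclass
class DiseaseSummary:
    """Disease-association summary of one gene set."""

    gene_set_size: int
    associated_count: int
    percentage: float  # 100*count/size, half-up to 1 decimal
    per_disease_counts: pd.Series

    @property
    def associated_genes(self) -> int:
        return self.associated_count


def filter_orthologs(links: PairTable, min_score: int = 12) -> PairTable:
    """Keep ortholog links supported by at least ``min_score`` databases."""
    if links.kind != "ortholog":
        raise ValueError("filter_orthologs expects an ortholog PairTable")
    kept = links.rows[links.rows["score"] >= min_score].reset_index(drop=True)
    return PairTable(kind="ortholog", rows=kept)


def gene_level_summary(
    spec: SpecificityMatrix,
    expr: ExpressionMatrix,
    tissue: str,
    aggregate: str = "max_specificity",
) -> pd.DataFrame:
    """Collapse transcripts to genes for one focal tissue.

    A gene's value is taken from its transcript with maximal normalized
    specificity in the tissue (default), preserving the enrichment signal;
    ``aggregate='mean'`` averages across the gene's transcripts instead.
    Returns per gene: specificity, tissue expression, exon_count and
    transcript_count.
    """
    norm = _require_normalized(spec)
    if tissue not in norm.columns:
        raise KeyError(f"unknown tissue {tissue!r}")
    df = pd.DataFrame(
        {
            "gene_id": expr.meta["gene_id"],
            "specificity": norm[tissue],
            "expression": expr.values[tissue],
            "exon_count": expr.meta["exon_count"],
        }
    )
    if aggregate == "max_specificity":
        picked = df.loc[df.groupby("gene_id")["specificity"].idxmax()]
        out = picked.set_index("gene_id")[["specificity", "expression", "exon_count"]]
    elif aggregate == "mean":
        out = df.groupby("gene_id")[["specificity", "expression", "exon_count"]].mean()
    else:
        raise ValueError(f"unknown aggregate {aggregate!r}")
    out["transcript_count"] = df.groupby("gene_id").size()
    return out


def join_cross_species(
    summary_a: pd.DataFrame, summary_b: pd.DataFrame, links: PairTable
) -> pd.DataFrame:
    """One row per surviving ortholog link, with both species' per-gene values.

    Links whose gene is absent from either summary are dropped (logged);
    many-to-many links yield one row per pair.
    """
    rows = links.rows
    present = rows["id_a"].isin(summary_a.index) & rows["id_b"].isin(summary_b.index)
    n_dropped = int((~present).sum())
    if n_dropped:
        logger.info("dropped %d ortholog links with a missing partner gene", n_dropped)
    kept = rows[present]
    joined = (
        kept.join(summary_a.add_suffix("_a"), on="id_a")
        .join(summary_b.add_suffix("_b"), on="id_b")
        .reset_index(drop=True)
    )
    return joined


def highly_enriched_gene_sets(
    assign: pd.DataFrame, meta: pd.DataFrame, tissues: list[str] | None = None
) -> dict[str, set[str]]:
    """Per tissue, the set of genes owning at least one highly enriched
    transcript there."""
    tissues = list(assign.columns) if tissues is None else tissues
    out = {}
    for tissue in tissues:
        if tissue not in assign.columns:
            raise KeyError(f"no categories for tissue {tissue!r}")
        hits = assign.index[assign[tissue] == "highly_enriched"]
        out[tissue] = set(meta.loc[hits, "gene_id"])
    return out


def venn_overlap(sets: dict[str, set]) -> VennResult:
    """Exact 2- or 3-set region decomposition."""
    names = list(sets)
    if len(names) not in (2, 3):
        raise ValueError("venn_overlap supports exactly 2 or 3 sets")
    universe = set().union(*sets.values())
    regions: dict[frozenset, set] = {}
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            inside = set.intersection(*(sets[n] for n in combo))
            outside = set().union(*(sets[n] for n in names if n not in combo)) if len(combo) < len(names) else set()
            members = inside - outside
            regions[frozenset(combo)] = members
    assert sum(len(v) for v in regions.values()) == len(universe)
    return VennResult(set_names=names, regions=regions)


def disease_summary(gene_set: set[str], disease_table: PairTable) -> DiseaseSummary:
    """Fraction of a gene set carrying at least one disease annotation.

    A gene counts once regardless of how many diseases it maps to; the
    percentage is rounded half-up to one decimal, matching how such fractions
    are conventionally printed (e.g. 118/318 -> 37.1).
    """
    if disease_table.kind != "disease":
        raise ValueError("disease_summary expects a disease PairTable")
    rows = disease_table.rows[disease_table.rows["id_a"].isin(gene_set)]
    associated = set(rows["id_a"])
    size = len(gene_set)
    pct = round_half_up(100 * len(associated) / size, 1) if size else 0.0
    per_disease = rows.groupby("id_b")["id_a"].nunique().sort_values(ascending=False)
    per_disease.index.name = "disease"
    return DiseaseSummary(
        gene_set_size=size,
        associated_count=len(associated),
        percentage=pct,
        per_disease_counts=per_disease,
    )


def disease_set(gene_set: set[str], disease_table: PairTable) -> set[str]:
    """The set of disease terms annotated to any gene of the set (for Venn
    overlap of diseases across tissues)."""
    rows = disease_table.rows[disease_table.rows["id_a"].isin(gene_set)]
    return set(rows["id_b"])
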