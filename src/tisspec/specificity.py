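"""The tissue-specificity statistic.

For each transcript with expression values e_1..e_n over n tissues, the raw
specificity in tissue i is the standardized expression

    x_i = (e_i - mean(e)) / sd(e),        sd = sample standard deviation (ddof=1)

so a transcript expressed in a single tissue reaches the closed-form maximum
(n-1)/sqrt(n) there.  Raw indices are then scaled to [-1, 1] by max-abs
scaling (per tissue column by default), where 1 marks the most
tissue-specific transcript of that tissue.  Transcripts are binned into four
enrichment categories by fixed thresholds on the scaled index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from tisspec.io_formats import ExpressionMatrix

CATEGORIES = ("underrepresented", "general", "enriched", "highly_enriched")


@dataclass
class SpecificityMatrix:
    """Raw and [-1,1]-normalized specificity indices per transcript per tissue."""

    raw: pd.DataFrame
    normalized: pd.DataFrame | None = None
    scope: str | None = None  # how normalization was applied: column | global

    @property
    def transcript_ids(self) -> list[str]:
        return list(self.raw.index)

    @property
    def tissue_names(self) -> list[str]:
        return list(self.raw.columns)


@dataclass(frozen=True)
class CategoryThresholds:
    """Boundaries of the four enrichment categories on the normalized index.

    Defaults: below -0.20 underrepresented; [-0.20, 0] general;
    (0, 0.80] enriched; above 0.80 highly enriched.
    """

    under_max: float = -0.20
    general_max: float = 0.00
    enriched_max: float = 0.80

    def __post_init__(self) -> None:
        if not (self.under_max < self.general_max < self.enriched_max < 1):
            raise ValueError("thresholds must satisfy under < general < enriched < 1")


def specificity_raw(expr: ExpressionMatrix) -> SpecificityMatrix:
    """Standardize each transcript's expression row across tissues.

    Rows with zero variance (including all-zero rows) get raw specificity 0
    everywhere: such transcripts are maximally non-specific.
    """
    if expr.n_tissues < 2:
        raise ValueError("specificity needs at least 2 tissues")
    v = expr.values.to_numpy(dtype=float)
    mean = v.mean(axis=1, keepdims=True)
    sd = v.std(axis=1, ddof=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        x = (v - mean) / sd
    x[np.broadcast_to(sd == 0, x.shape)] = 0.0
    raw = pd.DataFrame(x, index=expr.values.index, columns=expr.values.columns)
    return SpecificityMatrix(raw=raw)


def normalize_maxabs(spec: SpecificityMatrix, scope: str = "column") -> SpecificityMatrix:
    """Scale raw indices into [-1, 1] by dividing by the maximum absolute value.

    ``scope='column'`` (default) scales each tissue column by its own max-abs,
    so every tissue with any signal has a transcript at +/-1;
    ``scope='global'`` divides the whole matrix by one max-abs.
    A column (or matrix) whose max-abs is 0 stays all-zero.
    """
    x = spec.raw.to_numpy(dtype=float)
    if scope == "column":
        denom = np.abs(x).max(axis=0, keepdims=True)
    elif scope == "global":
        denom = np.array([[np.abs(x).max() if x.size else 0.0]])
    else:
        raise ValueError(f"unknown normalization scope {scope!r}")
    safe = np.where(denom == 0, 1.0, denom)
    normalized = pd.DataFrame(
        x / safe, index=spec.raw.index, columns=spec.raw.columns
    )
    return SpecificityMatrix(raw=spec.raw, normalized=normalized, scope=scope)


def compute_specificity(expr: ExpressionMatrix, scope: str = "column") -> SpecificityMatrix:
    """Convenience: raw standardization followed by max-abs scaling."""
    return normalize_maxabs(specificity_raw(expr), scope=scope)


def summarize_transcript(spec: SpecificityMatrix) -> pd.DataFrame:
    """Per-transcript max, median and argmax tissue of the normalized index.

    Argmax ties break lexicographically by tissue name for reproducibility.
    """
    norm = _require_normalized(spec)
    ordered = norm[sorted(norm.columns)]
    return pd.DataFrame(
        {
            "max_specificity": norm.max(axis=1),
            "median_specificity": norm.median(axis=1),
            "argmax_tissue": ordered.idxmax(axis=1),
        }
    )


def assign_categories(
    spec: SpecificityMatrix, thresholds: CategoryThresholds = CategoryThresholds()
) -> pd.DataFrame:
    """Label every (transcript, tissue) cell with one of the four categories."""
    norm = _require_normalized(spec)
    x = norm.to_numpy()
    t = thresholds
    labels = np.select(
        [x < t.under_max, x <= t.general_max, x <= t.enriched_max],
        ["underrepresented", "general", "enriched"],
        default="highly_enriched",
    )
    out = pd.DataFrame(labels, index=norm.index, columns=norm.columns)
    return out.astype(pd.CategoricalDtype(categories=list(CATEGORIES)))


def count_enriched(
    spec: SpecificityMatrix, tissue: str, threshold: float = 0.8
) -> tuple[int, float]:
    """Count transcripts whose normalized specificity exceeds ``threshold`` in
    one tissue; also return the fraction of all transcripts."""
    norm = _require_normalized(spec)
    if tissue not in norm.columns:
        raise KeyError(f"unknown tissue {tissue!r}")
    count = int((norm[tissue] > threshold).sum())
    return count, count / len(norm)


def exclude_tissues_recompute(
    expr: ExpressionMatrix, excluded: set[str] | list[str], scope: str = "column"
) -> SpecificityMatrix:
    """Drop tissues and recompute specificity from scratch on the remainder.

    The sample size n in the standardization becomes the reduced tissue count,
    so both the raw index and its attainable maximum change.
    """
    excluded = set(excluded)
    unknown = excluded - set(expr.tissue_names)
    if unknown:
        raise KeyError(f"tissues not in matrix: {sorted(unknown)}")
    remaining = [t for t in expr.tissue_names if t not in excluded]
    if len(remaining) < 2:
        raise ValueError("at least 2 tissues must remain after exclusion")
    return compute_specificity(expr.subset_tissues(remaining), scope=scope)


def filter_by_expression(expr: ExpressionMatrix, min_value: float = 5) -> ExpressionMatrix:
    """Keep transcripts whose maximum expression across tissues is >= min_value.

    Filters globally low expressors without penalizing tissue-restricted
    transcripts that are strong in a single tissue.
    """
    keep = expr.values.max(axis=1) >= min_value
    return ExpressionMatrix(expr.values.loc[keep].copy(), expr.meta.loc[keep].copy())


def specificity_histogram(
    spec: SpecificityMatrix, statistic: str = "max", bins: int = 40
) -> pd.DataFrame:
    """TSV-ready histogram of per-transcript max or median normalized
    specificity: columns bin_left, bin_right, count."""
    norm = _require_normalized(spec)
    values = norm.max(axis=1) if statistic == "max" else norm.median(axis=1)
    counts, edges = np.histogram(values.to_numpy(), bins=bins, range=(-1, 1))
    return pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
    )


def single_tissue_max(n: int) -> float:
    """Closed-form raw specificity of a transcript expressed in exactly one of
    n tissues: (n-1)/sqrt(n)."""
    return (n - 1) / np.sqrt(n)


def _require_normalized(spec: SpecificityMatrix) -> pd.DataFrame:
    if spec.normalized is None:
        raise ValueError("normalized specificity not computed; run normalize_maxabs")
    return spec.normalized
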