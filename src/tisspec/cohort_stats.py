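"""Per-category cohort summaries and the statistical machinery around them:
Welch's two-tailed t-test, 95% confidence intervals, and Pearson/Spearman
correlation matrices over expression, specificity, exon-count and
transcript-count features."""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from tisspec.io_formats import ExpressionMatrix
from tisspec.specificity import CATEGORIES

logger = logging.getLogger(__name__)

# significance stars used in reports; Welch tests are reported uncorrected
STARS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def significance_stars(p: float) -> str:
    for cutoff, mark in STARS:
        if p < cutoff:
            return mark
    return "n.s."


@dataclass
class CorrelationMatrix:
    """Symmetric coefficient matrix with matching p-values."""

    coefficients: pd.DataFrame
    p_values: pd.DataFrame
    method: str

    @property
    def feature_names(self) -> list[str]:
        return list(self.coefficients.columns)


def ci95_halfwidth(sample: np.ndarray) -> float:
    """Half-width of the mean's 95% CI using the t-distribution:
    t_{0.975, m-1} * sd / sqrt(m).  NaN for singleton samples."""
    m = len(sample)
    if m < 2:
        return float("nan")
    sd = np.std(sample, ddof=1)
    return float(stats.t.ppf(0.975, m - 1) * sd / np.sqrt(m))


def group_summary(
    assign: pd.DataFrame,
    expr: ExpressionMatrix,
    tissue: str,
    meta: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Summarize each enrichment category of one tissue.

    Returns one row per category with gene/transcript counts, mean and median
    of tissue expression and of maximum expression, mean/median exon count,
    the median number of transcripts per gene, and 95% CI half-widths of the
    means.  Empty categories yield NaN statistics (absent, not zero).
    """
    if tissue not in assign.columns:
        raise KeyError(f"no categories for tissue {tissue!r}")
    meta = expr.meta if meta is None else meta
    labels = assign[tissue]
    tissue_expr = expr.values[tissue]
    max_expr = expr.values.max(axis=1)
    tpg = meta.groupby("gene_id").size()  # transcripts per gene

    rows = []
    for cat in CATEGORIES:
        ids = labels.index[labels == cat]
        m = len(ids)
        row: dict[str, float] = {"category": cat, "transcript_count": m}
        if m == 0:
            rows.append(row)
            continue
        genes = meta.loc[ids, "gene_id"]
        te = tissue_expr.loc[ids].to_numpy()
        me = max_expr.loc[ids].to_numpy()
        ex = meta.loc[ids, "exon_count"].to_numpy(dtype=float)
        row.update(
            gene_count=genes.nunique(),
            mean_tissue_expression=te.mean(),
            median_tissue_expression=float(np.median(te)),
            ci95_tissue_expression=ci95_halfwidth(te),
            mean_max_expression=me.mean(),
            median_max_expression=float(np.median(me)),
            ci95_max_expression=ci95_halfwidth(me),
            mean_exon_count=ex.mean(),
            median_exon_count=float(np.median(ex)),
            ci95_exon_count=ci95_halfwidth(ex),
            median_transcripts_per_gene=float(tpg.loc[genes.unique()].median()),
        )
        rows.append(row)
    out = pd.DataFrame(rows).set_index("category")
    assert out["transcript_count"].sum() == len(labels)
    return out


def welch_t_test(a, b) -> tuple[float, float, float]:
    """Welch's two-tailed t-test.

    Returns (t, Welch-Satterthwaite df, two-sided p).  Requires >= 2
    observations per sample and a nonzero variance in at least one.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        raise ValueError("both samples have zero variance; t undefined")
    res = stats.ttest_ind(a, b, equal_var=False)
    se2a, se2b = va / len(a), vb / len(b)
    df = (se2a + se2b) ** 2 / (se2a**2 / (len(a) - 1) + se2b**2 / (len(b) - 1))
    return float(res.statistic), float(df), float(res.pvalue)


def pairwise_category_tests(
    assign: pd.DataFrame, values: pd.Series, tissue: str
) -> pd.DataFrame:
    """All pairwise Welch tests of a per-transcript feature between the four
    categories of one tissue, with significance stars."""
    labels = assign[tissue]
    rows = []
    for ca, cb in itertools.combinations(CATEGORIES, 2):
        va = values.loc[labels.index[labels == ca]].dropna().to_numpy()
        vb = values.loc[labels.index[labels == cb]].dropna().to_numpy()
        if len(va) < 2 or len(vb) < 2 or (va.var(ddof=1) == 0 and vb.var(ddof=1) == 0):
            rows.append({"a": ca, "b": cb, "t": np.nan, "df": np.nan, "p": np.nan, "stars": "n.a."})
            continue
        t, df, p = welch_t_test(va, vb)
        rows.append({"a": ca, "b": cb, "t": t, "df": df, "p": p, "stars": significance_stars(p)})
    return pd.DataFrame(rows)


def correlation_matrix(
    features: pd.DataFrame | dict, method: str | None = None
) -> CorrelationMatrix:
    """Pairwise correlation of named feature vectors over a shared index.

    Missing entries are removed pairwise; every pair needs >= 3 complete
    observations.  Spearman (average ranks for ties) is the default whenever a
    feature name looks like expression or specificity data; a constant vector
    yields NaN coefficients for its pairs rather than 0.
    """
    feats = pd.DataFrame(features)
    if method is None:
        datalike = any(
            any(tag in str(c).lower() for tag in ("exp", "sp", "specific"))
            for c in feats.columns
        )
        method = "spearman" if datalike else "pearson"
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation method {method!r}")
    corr_fn = stats.pearsonr if method == "pearson" else stats.spearmanr

    names = list(feats.columns)
    k = len(names)
    r = np.eye(k)
    p = np.zeros((k, k))
    for i, j in itertools.combinations(range(k), 2):
        pair = feats.iloc[:, [i, j]].dropna()
        if len(pair) < 3:
            raise ValueError(
                f"features {names[i]!r}/{names[j]!r}: need >= 3 shared observations"
            )
        x, y = pair.iloc[:, 0].to_numpy(), pair.iloc[:, 1].to_numpy()
        if np.all(x == x[0]) or np.all(y == y[0]):
            logger.info("constant vector in pair (%s, %s); coefficient absent", names[i], names[j])
            r[i, j] = r[j, i] = np.nan
            p[i, j] = p[j, i] = np.nan
            continue
        res = corr_fn(x, y)
        r[i, j] = r[j, i] = res.statistic
        p[i, j] = p[j, i] = res.pvalue
    idx = pd.Index(names)
    return CorrelationMatrix(
        coefficients=pd.DataFrame(r, index=idx, columns=idx),
        p_values=pd.DataFrame(p, index=idx, columns=idx),
        method=method,
    )
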