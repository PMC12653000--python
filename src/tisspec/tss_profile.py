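"""Strand-aware nucleotide-composition profiling around transcription start
sites (TSS).

The TSS of a transcript is the genomic position of its first nucleotide: the
annotation start on the + strand, end - 1 (0-based) on the - strand.
"Upstream" always means 5' of the transcript, so - strand flanks are
reverse-complemented.  Flanks of length U + D (U upstream, D downstream, the
TSS base at index U) are deduplicated exactly, then summarized as a
per-position A/T/G/C frequency matrix; positions running off a contig are
N-padded and N never enters a frequency denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from tisspec.io_formats import ExpressionMatrix, TranscriptAnnotation, write_fasta
from tisspec.specificity import SpecificityMatrix, _require_normalized

BASES = ("A", "T", "G", "C")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# motif-analysis windows: upstream 300 bp, and the core promoter split into
# 100 bp upstream / 100 bp downstream of the TSS
MOTIF_WINDOWS = {
    "upstream300": (300, 0),
    "upstream100": (100, 0),
    "downstream100": (0, 100),
}


@dataclass(frozen=True)
class TSSRecord:
    transcript_id: str
    chrom: str
    tss: int  # 0-based genomic position of the first transcribed base
    strand: str


@dataclass
class FlankSet:
    """Unique, equal-length, transcript-strand-oriented flank sequences."""

    upstream: int
    downstream: int
    sequences: list[str]
    counts: list[int]  # how many input records collapsed per unique sequence

    def __post_init__(self) -> None:
        width = self.upstream + self.downstream
        if any(len(s) != width for s in self.sequences):
            raise ValueError("all flank sequences must have length U + D")


@dataclass
class BaseProfile:
    """Per-position base frequencies over a TSS-centered window.

    ``frequencies`` is indexed by position (-U .. D-1 relative to the TSS) with
    one column per base; ``counts`` holds the non-N observation count per
    position.  Positions covered only by N have NaN frequencies.
    """

    frequencies: pd.DataFrame
    counts: pd.Series

    @property
    def positions(self) -> np.ndarray:
        return self.frequencies.index.to_numpy()


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def tss_coordinates(annotations: list[TranscriptAnnotation]) -> list[TSSRecord]:
    """First-nucleotide positions from internal 0-based half-open intervals."""
    out = []
    for a in annotations:
        if a.strand not in ("+", "-"):
            raise ValueError(f"{a.transcript_id}: missing strand")
        tss = a.start if a.strand == "+" else a.end - 1
        out.append(TSSRecord(a.transcript_id, a.chrom, tss, a.strand))
    return out


def extract_flank(genome: dict[str, str], rec: TSSRecord, upstream: int, downstream: int) -> str:
    """Oriented flank of length U + D with the TSS base at index U.

    + strand: genome[tss-U : tss+D]; - strand: reverse complement of
    genome[tss-D+1 : tss+U+1].  Positions beyond the contig are 'N'.
    """
    if rec.chrom not in genome:
        raise KeyError(f"chrom {rec.chrom!r} not in genome")
    contig = genome[rec.chrom]
    if rec.strand == "+":
        lo, hi = rec.tss - upstream, rec.tss + downstream
    else:
        lo, hi = rec.tss - downstream + 1, rec.tss + upstream + 1
    left_pad = max(0, -lo)
    right_pad = max(0, hi - len(contig))
    seq = "N" * left_pad + contig[max(0, lo) : min(hi, len(contig))].upper() + "N" * right_pad
    if rec.strand == "-":
        seq = reverse_complement(seq)
    return seq


def extract_flanks(
    genome: dict[str, str],
    records: list[TSSRecord],
    upstream: int,
    downstream: int,
    dedup: bool = True,
) -> FlankSet:
    seqs = [extract_flank(genome, r, upstream, downstream) for r in records]
    if dedup:
        return dedup_sequences(seqs, upstream=upstream, downstream=downstream)
    return FlankSet(upstream, downstream, seqs, [1] * len(seqs))


def dedup_sequences(
    seqs: list[str], upstream: int | None = None, downstream: int | None = None
) -> FlankSet:
    """Exact-string deduplication (after uppercasing), first-seen order."""
    lengths = {len(s) for s in seqs}
    if len(lengths) > 1:
        raise ValueError(f"mixed sequence lengths: {sorted(lengths)}")
    width = lengths.pop() if lengths else 0
    if upstream is None:
        upstream, downstream = width, 0
    seen: dict[str, int] = {}
    for s in seqs:
        s = s.upper()
        seen[s] = seen.get(s, 0) + 1
    return FlankSet(upstream, downstream or 0, list(seen), list(seen.values()))


def base_profile(flanks: FlankSet, smooth_window: int = 1) -> BaseProfile:
    """Per-position A/T/G/C frequency among non-N observations.

    ``smooth_window`` > 1 applies a centered moving average for plotting
    parity; counts are left unsmoothed.
    """
    if not flanks.sequences:
        raise ValueError("cannot profile an empty flank set")
    arr = np.frombuffer(
        "".join(flanks.sequences).encode(), dtype="S1"
    ).reshape(len(flanks.sequences), -1)
    positions = np.arange(-flanks.upstream, flanks.downstream)
    base_counts = {b: (arr == b.encode()).sum(axis=0) for b in BASES}
    non_n = sum(base_counts.values())
    with np.errstate(divide="ignore", invalid="ignore"):
        freqs = {b: np.where(non_n > 0, c / np.maximum(non_n, 1), np.nan) for b, c in base_counts.items()}
    df = pd.DataFrame(freqs, index=pd.Index(positions, name="position"))
    if smooth_window > 1:
        df = df.rolling(smooth_window, center=True, min_periods=1).mean()
    return BaseProfile(frequencies=df, counts=pd.Series(non_n, index=df.index))


def control_set(spec: SpecificityMatrix, threshold: float = 0.8) -> list[str]:
    """Transcripts with no high enrichment anywhere: max normalized
    specificity <= threshold in every tissue of their species."""
    norm = _require_normalized(spec)
    keep = norm.max(axis=1) <= threshold
    return list(norm.index[keep])


def control_gene_background(
    spec: SpecificityMatrix, meta: pd.DataFrame, threshold: float = 0.8
) -> list[str]:
    """Transcripts of genes that lack any highly enriched transcript variant
    (the motif-analysis background)."""
    norm = _require_normalized(spec)
    enriched_genes = set(meta.loc[norm.index[norm.max(axis=1) > threshold], "gene_id"])
    keep = ~meta.loc[norm.index, "gene_id"].isin(enriched_genes)
    return list(norm.index[keep.to_numpy()])


def select_noncoding(
    annotations: list[TranscriptAnnotation],
    enriched_transcripts: set[str],
    min_set_size: int = 50,
) -> dict[str, object]:
    """Partition non-coding transcripts into tissue-enriched vs all other.

    Sets smaller than ``min_set_size`` are refused (too few sequences for a
    stable profile) and flagged in the returned report.
    """
    noncoding = [a for a in annotations if a.biotype == "noncoding"]
    enriched = [a for a in noncoding if a.transcript_id in enriched_transcripts]
    other = [a for a in noncoding if a.transcript_id not in enriched_transcripts]
    report = {}
    for name, group in (("enriched", enriched), ("other", other)):
        ok = len(group) >= min_set_size
        report[name] = {
            "annotations": group if ok else [],
            "n": len(group),
            "profiled": ok,
            "note": "" if ok else (
                f"{name}: only {len(group)} non-coding sequences "
                f"(< {min_set_size}); too few to profile"
            ),
        }
    return report


def _aligned_freq_vectors(p: BaseProfile, q: BaseProfile) -> tuple[pd.DataFrame, pd.DataFrame]:
    if not np.array_equal(p.positions, q.positions):
        raise ValueError("profiles cover different position ranges")
    return p.frequencies, q.frequencies


def profile_distance(p: BaseProfile, q: BaseProfile) -> dict:
    """MSE and Euclidean distance between two profiles.

    Computed over the concatenated per-base frequency vectors (pooled) and per
    base; NaN positions (all-N) are excluded pairwise.
    """
    fp, fq = _aligned_freq_vectors(p, q)
    out: dict = {"per_base": {}}
    diffs = []
    for b in BASES:
        d = (fp[b] - fq[b]).dropna().to_numpy()
        out["per_base"][b] = {
            "mse": float(np.mean(d**2)) if d.size else float("nan"),
            "euclidean": float(np.linalg.norm(d)),
        }
        diffs.append(d)
    pooled = np.concatenate(diffs)
    out["mse"] = float(np.mean(pooled**2)) if pooled.size else float("nan")
    out["euclidean"] = float(np.linalg.norm(pooled))
    return out


def profile_correlation(
    p: BaseProfile,
    q: BaseProfile,
    method: str = "pearson",
    window: tuple[int, int] | None = None,
) -> dict:
    """Per-base correlation of two profiles across positions.

    ``window=(lo, hi)`` restricts to positions lo <= pos < hi (e.g. an
    upstream-only or TSS-centered sub-window).  Constant vectors yield NaN
    (flagged absent), not 0.
    """
    fp, fq = _aligned_freq_vectors(p, q)
    if window is not None:
        lo, hi = window
        mask = (fp.index >= lo) & (fp.index < hi)
        fp, fq = fp[mask], fq[mask]
    corr_fn = stats.pearsonr if method == "pearson" else stats.spearmanr
    out: dict = {"per_base": {}, "window": window}
    pooled_x, pooled_y = [], []
    for b in BASES:
        pair = pd.DataFrame({"x": fp[b], "y": fq[b]}).dropna()
        x, y = pair["x"].to_numpy(), pair["y"].to_numpy()
        if len(x) < 3 or np.all(x == x[0]) or np.all(y == y[0]):
            out["per_base"][b] = float("nan")
        else:
            out["per_base"][b] = float(corr_fn(x, y).statistic)
        pooled_x.append(x)
        pooled_y.append(y)
    x = np.concatenate(pooled_x)
    y = np.concatenate(pooled_y)
    out["pooled"] = (
        float(corr_fn(x, y).statistic)
        if len(x) >= 3 and not (np.all(x == x[0]) or np.all(y == y[0]))
        else float("nan")
    )
    return out


def export_motif_windows(
    genome: dict[str, str],
    target_records: list[TSSRecord],
    background_records: list[TSSRecord],
    out_dir,
    windows: dict[str, tuple[int, int]] | None = None,
    label: str = "target",
) -> dict[str, str]:
    """Write per-window FASTA files of unique target and background flanks,
    ready for external motif-discovery tools.  Returns {name: path}."""
    from pathlib import Path

    windows = MOTIF_WINDOWS if windows is None else windows
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = {}
    for win_name, (u, d) in windows.items():
        for set_name, records in ((label, target_records), ("background", background_records)):
            flanks = extract_flanks(genome, records, u, d, dedup=True)
            seqs = {
                f"{set_name}_{win_name}_{i:05d}": s
                for i, s in enumerate(flanks.sequences)
            }
            path = out_dir / f"{set_name}_{win_name}.fasta"
            write_fasta(seqs, path)
            written[f"{set_name}_{win_name}"] = str(path)
    return written


def profile_to_frame(profile: BaseProfile) -> pd.DataFrame:
    """TSV-ready long table: position, A, T, G, C, count."""
    df = profile.frequencies.copy()
    df["count"] = profile.counts
    return df.reset_index()
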