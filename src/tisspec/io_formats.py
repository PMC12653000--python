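"""Readers and writers for the tabular, annotation and sequence formats the
pipeline touches.

All genomic intervals are stored 0-based half-open internally; conversion from
GTF (1-based closed) happens at the I/O boundary and nowhere else.  All text
inputs are read gzip-transparently (a ``.gz`` suffix or gzip magic bytes both
work).
"""

from __future__ import annotations

import gzip
import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

VALID_BIOTYPES = ("coding", "noncoding")
FASTA_ALPHABET = frozenset("ACGTN")


def _open_text(path: str | Path):
    """Open a possibly-gzipped text file for reading."""
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


@dataclass
class ExpressionMatrix:
    """Transcripts x tissues non-negative expression values plus metadata.

    Attributes
    ----------
    values : pd.DataFrame
        Rows indexed by transcript id, columns are tissue names; FPKM/TPM-like
        non-negative reals.
    meta : pd.DataFrame
        Indexed like ``values``; columns ``gene_id``, ``exon_count``,
        ``biotype`` (coding/noncoding) and ``species``.
    """

    values: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicate transcript ids: {dupes[:5]}")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")
        if self.values.shape[1] < 2:
            raise ValueError("need at least 2 tissues")
        if not self.meta.index.equals(self.values.index):
            self.meta = self.meta.reindex(self.values.index)
        if self.meta["gene_id"].isna().any():
            raise ValueError("every transcript needs a gene_id")

    @property
    def transcript_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def tissue_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_tissues(self) -> int:
        return self.values.shape[1]

    def subset_tissues(self, tissues: Sequence[str]) -> "ExpressionMatrix":
        missing = [t for t in tissues if t not in self.values.columns]
        if missing:
            raise KeyError(f"unknown tissues: {missing}")
        return ExpressionMatrix(self.values[list(tissues)].copy(), self.meta.copy())


@dataclass(frozen=True)
class TranscriptAnnotation:
    """One transcript's genomic footprint, 0-based half-open."""

    transcript_id: str
    chrom: str
    start: int
    end: int
    strand: str
    gene_id: str
    biotype: str = "coding"
    exon_count: int = 1

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(
                f"{self.transcript_id}: strand must be '+' or '-', got {self.strand!r}"
            )
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"{self.transcript_id}: invalid interval [{self.start}, {self.end})"
            )
        if self.exon_count < 1:
            raise ValueError(f"{self.transcript_id}: exon_count must be >= 1")


@dataclass
class PairTable:
    """Typed gene-pair rows: ortholog links (scored), physical edges, or
    gene->disease annotations."""

    kind: str
    rows: pd.DataFrame  # columns: id_a, id_b, and score for orthologs

    def __post_init__(self) -> None:
        if self.kind not in ("ortholog", "physical", "disease"):
            raise ValueError(f"unknown pair-table kind {self.kind!r}")
        if self.kind == "ortholog" and "score" not in self.rows.columns:
            raise ValueError("ortholog table requires a score column")


def read_expression_table(
    path: str | Path,
    replicate_groups: Mapping[str, Sequence[str]] | None = None,
    species: str = "unknown",
    meta_columns: Mapping[str, str] | None = None,
    id_normalizer=None,
) -> ExpressionMatrix:
    """Read a per-tissue expression TSV, averaging replicate columns at ingest.

    The file must have a header; the first column is the transcript id.
    Recognized metadata columns (``gene_id``, ``exon_count``, ``biotype``) are
    split off; every remaining column is treated as a tissue.

    Parameters
    ----------
    replicate_groups
        Maps an output tissue name to the source columns whose arithmetic mean
        forms it (replicate samples of the same tissue in the source atlas).
        Columns not mentioned pass through unchanged.
    id_normalizer
        Optional callable applied to every transcript id (e.g. to strip
        Ensembl version suffixes before joining to annotation).
    """
    with _open_text(path) as fh:
        df = pd.read_csv(fh, sep="\t", dtype={0: str})
    id_col = df.columns[0]
    df = df.set_index(id_col)
    if id_normalizer is not None:
        df.index = df.index.map(id_normalizer)
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].tolist()
        raise ValueError(f"duplicate transcript ids in {path}: {dupes[:5]}")

    meta_names = {"gene_id", "exon_count", "biotype"}
    meta_cols = [c for c in df.columns if c in meta_names]
    expr = df.drop(columns=meta_cols).astype(float)

    n_missing = int(expr.isna().to_numpy().sum())
    if n_missing:
        logger.info("treating %d missing expression cells as 0", n_missing)
        expr = expr.fillna(0.0)

    neg = expr.lt(0).any(axis=1)
    if neg.any():
        # +2: header line plus 1-based numbering
        bad_line = int(np.nonzero(neg.to_numpy())[0][0]) + 2
        raise ValueError(
            f"negative expression value at line {bad_line} "
            f"(transcript {expr.index[neg][0]!r}) in {path}"
        )

    if replicate_groups:
        grouped = {}
        consumed: set[str] = set()
        for tissue, cols in replicate_groups.items():
            missing = [c for c in cols if c not in expr.columns]
            if missing:
                raise KeyError(f"replicate columns not in file: {missing}")
            grouped[tissue] = expr[list(cols)].mean(axis=1)
            consumed.update(cols)
        rest = [c for c in expr.columns if c not in consumed]
        expr = pd.concat([pd.DataFrame(grouped), expr[rest]], axis=1)

    meta = pd.DataFrame(index=expr.index)
    meta["gene_id"] = df["gene_id"] if "gene_id" in meta_cols else expr.index
    meta["exon_count"] = (
        df["exon_count"].astype(int) if "exon_count" in meta_cols else 1
    )
    meta["biotype"] = df["biotype"] if "biotype" in meta_cols else "coding"
    meta["species"] = species
    return ExpressionMatrix(expr, meta)


def _parse_gtf(text: str) -> list[TranscriptAnnotation]:
    db = gffutils.create_db(
        text,
        ":memory:",
        from_string=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    out = []
    for t in db.features_of_type("transcript"):
        if t.strand not in ("+", "-"):
            raise ValueError(f"transcript {t.id}: missing strand")
        exons = list(db.children(t, featuretype="exon"))
        biotype = "coding"
        for key in ("transcript_biotype", "gene_biotype", "biotype"):
            if key in t.attributes:
                raw = t.attributes[key][0]
                biotype = "coding" if "coding" in raw and "non" not in raw else (
                    "noncoding" if raw in ("noncoding", "ncRNA") or "non" in raw else "coding"
                )
                break
        out.append(
            TranscriptAnnotation(
                transcript_id=t.id,
                chrom=t.seqid,
                start=t.start - 1,  # GTF is 1-based closed
                end=t.end,
                strand=t.strand,
                gene_id=t.attributes.get("gene_id", [t.id])[0],
                biotype=biotype,
                exon_count=max(1, len(exons)),
            )
        )
    return out


def _parse_bed(text: str) -> list[TranscriptAnnotation]:
    out = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        f = line.split("\t")
        if len(f) < 6:
            raise ValueError(f"BED line {lineno}: need >= 6 columns for strand")
        chrom, start, end, name, _score, strand = f[:6]
        exon_count = int(f[9]) if len(f) >= 12 else 1  # BED12 blockCount
        out.append(
            TranscriptAnnotation(
                transcript_id=name,
                chrom=chrom,
                start=int(start),
                end=int(end),
                strand=strand,
                gene_id=name,
                exon_count=exon_count,
            )
        )
    return out


def read_annotation(path: str | Path, dialect: str = "gtf") -> list[TranscriptAnnotation]:
    """Read transcript annotation from GTF or BED into internal 0-based
    half-open coordinates.

    GTF ``transcript`` features become records; their ``exon`` children are
    counted.  BED12 block counts are used as exon counts.
    """
    with _open_text(path) as fh:
        text = fh.read()
    if dialect == "gtf":
        return _parse_gtf(text)
    if dialect == "bed":
        return _parse_bed(text)
    raise ValueError(f"unknown annotation dialect {dialect!r}")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into a chrom -> uppercase sequence map."""
    genome: dict[str, str] = {}
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in genome:
                raise ValueError(f"duplicate chrom name {rec.id!r} in {path}")
            genome[rec.id] = str(rec.seq).upper()
    if not genome:
        raise ValueError(f"no FASTA records in {path}")
    return genome


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    """Write named sequences as 60-column-wrapped FASTA (byte-stable)."""
    names = list(sequences)
    if len(set(names)) != len(names):
        raise ValueError("duplicate sequence names")
    records = []
    for name, seq in sequences.items():
        seq = seq.upper()
        bad = set(seq) - FASTA_ALPHABET
        if bad:
            raise ValueError(f"illegal characters {sorted(bad)} in sequence {name!r}")
        records.append(SeqRecord(Seq(seq), id=name, description=""))
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(records)


def read_pair_table(path: str | Path, kind: str) -> PairTable:
    """Read a two-or-three column TSV of gene pairs.

    ``ortholog`` rows require an integer score column; ``physical`` self-loops
    are dropped (logged); ``disease`` rows are gene -> free-text term.
    """
    with _open_text(path) as fh:
        df = pd.read_csv(fh, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: pair table needs at least 2 columns")
    df = df.rename(columns=dict(zip(df.columns[:3], ["id_a", "id_b", "score"])))
    if kind == "ortholog":
        if "score" not in df.columns:
            raise ValueError("ortholog table requires a score column")
        scores = pd.to_numeric(df["score"], errors="coerce")
        if scores.isna().any() or (scores != scores.round()).any():
            bad = df.loc[scores.isna() | (scores != scores.round()), "score"]
            raise ValueError(f"non-integer DIOPT score(s): {bad.head().tolist()}")
        df["score"] = scores.astype(int)
    elif kind == "physical":
        self_loops = df["id_a"] == df["id_b"]
        if self_loops.any():
            logger.info("dropped %d physical self-loops", int(self_loops.sum()))
            df = df[~self_loops]
        df = df[["id_a", "id_b"]]
    elif kind == "disease":
        df = df[["id_a", "id_b"]]
    return PairTable(kind=kind, rows=df.reset_index(drop=True))
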