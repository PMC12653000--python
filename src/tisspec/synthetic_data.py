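"""Seeded generators for every input the pipeline consumes.

The generators emulate the shape of the real inputs — two multi-tissue
expression atlases (33 "human-like" and 17 "fly-like" tissues), genomes with
annotated transcripts whose promoters carry planted composition signals (a GC
rise approaching the TSS, an AT peak ~25 bp upstream, a downstream T/G
excess), DIOPT-style scored ortholog links, physical-interaction edge lists
with designated hubs, and gene-disease annotations — and return ground-truth
labels alongside, so every stage of the analysis can be checked for parameter
recovery.  All randomness flows from one explicit seed per generator call;
identical seeds reproduce identical outputs byte for byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from tisspec.io_formats import ExpressionMatrix, PairTable

HUMAN_TISSUES = (
    "adipose", "adrenal_gland", "artery", "bladder", "blood", "bone_marrow",
    "brain", "breast", "cervix", "colon", "esophagus", "fallopian_tube",
    "heart", "kidney", "liver", "lung", "lymph_node", "muscle", "nerve",
    "ovary", "pancreas", "pituitary", "prostate", "salivary_gland", "skin",
    "small_intestine", "spleen", "stomach", "testis", "thyroid", "tonsil",
    "uterus", "vagina",
)  # n = 33
FLY_TISSUES = (
    "accessory_gland", "adipose", "brain", "carcass", "crop", "eye", "head",
    "heart", "hindgut", "malpighian_tubule", "midgut", "ovary", "rectal_pad",
    "salivary_gland", "testis", "thoracic_ganglion", "trachea",
)  # n = 17

# mean transcripts per gene in the two emulated atlases
SPECIES_STYLES = {
    "human": {"tissues": HUMAN_TISSUES, "transcripts_per_gene": 3.4, "mean_exons": 8.0},
    "fly": {"tissues": FLY_TISSUES, "transcripts_per_gene": 2.2, "mean_exons": 4.0},
}


@dataclass
class PromoterSignal:
    """Planted promoter composition, all excesses as absolute frequency shifts
    over the background on the transcript strand.

    gc_rise: extra G+C in [-100, 0) before the TSS.
    at_peak: extra A+T in the band -30..-20 (an AT peak centered at -25).
    t_excess / g_excess: extra T and G over ``downstream_len`` bases after
    the TSS (the transcription-associated skew).
    """

    background_gc: float = 0.42
    gc_rise: float = 0.15
    at_peak: float = 0.20
    t_excess: float = 0.05
    g_excess: float = 0.05
    downstream_len: int = 500

    def base_probs(self, rel: int) -> np.ndarray:
        """Probability of (A, C, G, T) at position ``rel`` relative to the TSS
        on the transcript strand."""
        gc = self.background_gc
        p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
        if -30 <= rel <= -20:
            at = (1 - gc) + self.at_peak
            p = np.array([at / 2, (1 - at) / 2, (1 - at) / 2, at / 2])
        elif -100 <= rel < 0:
            g = gc + self.gc_rise
            p = np.array([(1 - g) / 2, g / 2, g / 2, (1 - g) / 2])
        elif 0 <= rel < self.downstream_len:
            p = p + np.array([0.0, 0.0, self.g_excess, self.t_excess])
            p[0] -= (self.t_excess + self.g_excess) / 2
            p[1] -= (self.t_excess + self.g_excess) / 2
        return p / p.sum()


@dataclass
class SyntheticTruth:
    """Ground-truth labels for one generated artifact."""

    seed: int
    planted: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        def default(o):
            if isinstance(o, (set, frozenset)):
                return sorted(o)
            if isinstance(o, np.integer):
                return int(o)
            if isinstance(o, np.floating):
                return float(o)
            return str(o)

        Path(path).write_text(json.dumps(asdict(self), indent=1, default=default, sort_keys=True))


def _gene_map(rng: np.random.Generator, n_transcripts: int, mean_tpg: float, prefix: str) -> pd.Series:
    """Assign transcripts to genes; gene sizes 1 + Poisson(mean - 1)."""
    sizes = []
    total = 0
    while total < n_transcripts:
        s = 1 + rng.poisson(mean_tpg - 1)
        sizes.append(min(s, n_transcripts - total))
        total += sizes[-1]
    genes = np.repeat([f"{prefix}G{i:05d}" for i in range(len(sizes))], sizes)
    return pd.Series(genes)


def gen_expression(
    n_transcripts: int = 2000,
    species: str = "human",
    plan: dict[str, tuple[int, float]] | None = None,
    meanlog: float = 1.0,
    sdlog: float = 1.0,
    seed: int = 0,
    tissues: tuple[str, ...] | None = None,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Simulate an FPKM/TPM-like expression matrix with planted enrichment.

    Background expression is log-normal (right-skewed, like atlas FPKM/TPM).
    ``plan`` maps a tissue to (count, fold): that many transcripts get their
    expression in the tissue raised to ``fold`` times the background median
    (or ``fold`` times their own value if that is larger), so every planted
    transcript is genuinely fold-enriched over typical background.  Planted
    sets are disjoint across tissues.  Default plan: 50 testis transcripts at
    fold 100.
    """
    style = SPECIES_STYLES[species]
    tissues = tuple(style["tissues"]) if tissues is None else tuple(tissues)
    if len(tissues) < 2:
        raise ValueError("need at least 2 tissues")
    plan = {"testis": (50, 100.0)} if plan is None else plan
    total_planted = sum(c for c, _ in plan.values())
    if total_planted > n_transcripts:
        raise ValueError("planted count exceeds n_transcripts")
    for t in plan:
        if t not in tissues:
            raise KeyError(f"plan tissue {t!r} not in tissue list")
    for _, (count, fold) in plan.items():
        if fold < 1:
            raise ValueError("fold must be >= 1")

    rng = np.random.default_rng(seed)
    values = rng.lognormal(mean=meanlog, sigma=sdlog, size=(n_transcripts, len(tissues)))

    ids = [f"{species[0].upper()}T{i:05d}" for i in range(n_transcripts)]
    pool = rng.permutation(n_transcripts)
    offset = 0
    planted: dict[str, list[str]] = {}
    col = {t: j for j, t in enumerate(tissues)}
    background_median = float(np.exp(meanlog))
    for tissue, (count, fold) in sorted(plan.items()):
        rows = pool[offset : offset + count]
        offset += count
        values[rows, col[tissue]] = fold * np.maximum(
            values[rows, col[tissue]], background_median
        )
        planted[tissue] = sorted(ids[r] for r in rows)

    genes = _gene_map(rng, n_transcripts, style["transcripts_per_gene"], species[0].upper())
    exons = 1 + rng.poisson(style["mean_exons"] - 1, size=n_transcripts)
    meta = pd.DataFrame(
        {
            "gene_id": genes.to_numpy(),
            "exon_count": exons,
            "biotype": np.where(rng.random(n_transcripts) < 0.25, "noncoding", "coding"),
            "species": species,
        },
        index=pd.Index(ids, name="transcript_id"),
    )
    expr = ExpressionMatrix(
        pd.DataFrame(values, index=meta.index, columns=list(tissues)), meta
    )
    truth = SyntheticTruth(
        seed=seed,
        planted={"enriched": planted, "plan": {t: list(p) for t, p in plan.items()}},
    )
    return expr, truth


def gen_genome_annotation(
    n_transcripts: int = 100,
    contig_length: int | None = None,
    signal: PromoterSignal | None = None,
    seed: int = 0,
    species: str = "human",
    upstream_margin: int = 1200,
    transcript_length: int = 1000,
    noncoding_fraction: float = 0.25,
    chrom: str = "chrS1",
    transcript_ids: list[str] | None = None,
    gene_ids: list[str] | None = None,
) -> tuple[dict[str, str], str, SyntheticTruth]:
    """Simulate a contig plus GTF with planted promoter composition.

    Each transcript occupies a non-overlapping slot; roughly half land on the
    minus strand, with their signal planted on the transcript strand (so it is
    only recoverable by strand-aware extraction).  Returns (genome dict,
    GTF text, truth).
    """
    signal = PromoterSignal() if signal is None else signal
    if transcript_ids is not None:
        if len(transcript_ids) != n_transcripts:
            n_transcripts = len(transcript_ids)
        if gene_ids is not None and len(gene_ids) != len(transcript_ids):
            raise ValueError("gene_ids must parallel transcript_ids")
    stride = upstream_margin + transcript_length + 200
    needed = stride * n_transcripts + 2 * stride
    if contig_length is None:
        contig_length = needed
    if contig_length < needed:
        raise ValueError(
            f"contig_length {contig_length} too short for {n_transcripts} "
            f"non-overlapping transcripts (need {needed})"
        )
    rng = np.random.default_rng(seed)
    gc = signal.background_gc
    bases = np.array(list("ACGT"))
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    genome_arr = rng.choice(4, size=contig_length, p=probs)

    comp = np.array([3, 2, 1, 0])  # A<->T, C<->G in ACGT index space
    rel_lo, rel_hi = -upstream_margin, signal.downstream_len
    prob_matrix = np.array([signal.base_probs(rel) for rel in range(rel_lo, rel_hi)])
    cum_fwd = prob_matrix.cumsum(axis=1)
    cum_rev = prob_matrix[:, comp].cumsum(axis=1)

    records = []
    truth_tx = {}
    gtf_lines = []
    for i in range(n_transcripts):
        strand = "+" if rng.random() < 0.5 else "-"
        slot = stride * (i + 1)
        tx_id = transcript_ids[i] if transcript_ids else f"{species[0].upper()}T{i:05d}"
        gene_id = gene_ids[i] if gene_ids else f"{species[0].upper()}G{i:05d}"
        if strand == "+":
            tss = slot
            start0, end0 = tss, tss + transcript_length
        else:
            tss = slot + transcript_length - 1
            start0, end0 = slot, tss + 1
        # plant position-specific composition on the transcript strand
        rels = np.arange(rel_lo, rel_hi)
        u = rng.random(len(rels))
        if strand == "+":
            gpos = tss + rels
            drawn = (u[:, None] > cum_fwd).sum(axis=1)
        else:
            gpos = tss - rels
            drawn = (u[:, None] > cum_rev).sum(axis=1)
        genome_arr[gpos] = drawn

        biotype = "noncoding" if rng.random() < noncoding_fraction else "protein_coding"
        exon_count = int(1 + rng.integers(0, 5))
        attrs = (
            f'gene_id "{gene_id}"; transcript_id "{tx_id}"; '
            f'transcript_biotype "{biotype}";'
        )
        gtf_lines.append(
            f"{chrom}\ttisspec_synth\ttranscript\t{start0 + 1}\t{end0}\t.\t{strand}\t.\t{attrs}"
        )
        bounds = np.linspace(start0, end0, exon_count + 1, dtype=int)
        for e in range(exon_count):
            gtf_lines.append(
                f"{chrom}\ttisspec_synth\texon\t{bounds[e] + 1}\t{bounds[e + 1]}\t.\t{strand}\t.\t{attrs}"
            )
        truth_tx[tx_id] = {"tss": int(tss), "strand": strand, "biotype": biotype}

    byte_map = np.frombuffer(b"ACGT", dtype=np.uint8)
    genome = {chrom: byte_map[genome_arr].tobytes().decode("ascii")}
    gtf_text = "\n".join(gtf_lines) + "\n"
    truth = SyntheticTruth(
        seed=seed,
        planted={
            "transcripts": truth_tx,
            "signal": asdict(signal),
            "at_peak_positions": [-30, -20],
        },
    )
    return genome, gtf_text, truth


def gen_links(
    genes_a: list[str],
    genes_b: list[str],
    ortholog_fraction: float = 0.5,
    score_low: int = 1,
    score_high: int = 15,
    n_hubs: int = 5,
    hub_degree: int = 25,
    background_edges_per_gene: float = 1.0,
    max_background_degree: int = 10,
    disease_fraction: float = 0.3,
    n_disease_terms: int = 40,
    seed: int = 0,
    hub_universe: list[str] | None = None,
) -> tuple[dict, SyntheticTruth]:
    """Simulate ortholog links, physical-interaction edges and disease labels.

    Ortholog links pair a fraction of species-A genes with distinct species-B
    genes, scored with integers drawn uniformly from [score_low, score_high].
    Physical edges per species combine ``n_hubs`` designated hub genes of
    exact degree ``hub_degree`` (planted in species A) with a sparse random
    background whose per-node degree never exceeds ``max_background_degree``
    plus one edge per hub — so with hub_degree > 20 and the defaults, the
    strict degree > 20 filter isolates exactly the planted hubs.
    ``hub_universe`` restricts the genes among which hubs and their partners
    are wired (e.g. to genes known to enter the network).
    ``disease_fraction`` of species-B genes get 1-3 disease terms.
    """
    if not 0 <= ortholog_fraction <= 1 or not 0 <= disease_fraction <= 1:
        raise ValueError("fractions must be in [0, 1]")
    rng = np.random.default_rng(seed)

    n_pairs = round(ortholog_fraction * min(len(genes_a), len(genes_b)))
    a_perm = rng.permutation(genes_a)
    b_perm = rng.permutation(genes_b)
    scores = rng.integers(score_low, score_high + 1, size=n_pairs)
    ortho_rows = pd.DataFrame(
        {"id_a": a_perm[:n_pairs], "id_b": b_perm[:n_pairs], "score": scores}
    ).sort_values(["id_a", "id_b"]).reset_index(drop=True)

    def physical_for(genes: list[str], plant_hubs: bool) -> tuple[pd.DataFrame, list[str]]:
        genes = list(genes)
        hub_genes: list[str] = []
        edges: set[tuple[str, str]] = set()
        degree: dict[str, int] = {g: 0 for g in genes}
        if plant_hubs and n_hubs > 0:
            universe = list(hub_universe) if hub_universe is not None else genes
            if any(g not in degree for g in universe):
                raise ValueError("hub_universe must be a subset of the gene list")
            if hub_degree >= len(universe) - n_hubs:
                raise ValueError("not enough genes to wire the requested hubs")
            picked = rng.choice(len(universe), size=n_hubs, replace=False)
            hub_genes = sorted(universe[i] for i in picked)
            non_hubs = [g for g in universe if g not in set(hub_genes)]
            for hub in hub_genes:
                partners = rng.choice(len(non_hubs), size=hub_degree, replace=False)
                for j in partners:
                    e = tuple(sorted((hub, non_hubs[j])))
                    edges.add(e)
                    degree[non_hubs[j]] += 1
                degree[hub] = hub_degree
        n_background = round(background_edges_per_gene * len(genes))
        target = len(edges) + n_background
        hub_set = set(hub_genes)
        attempts = 0
        while len(edges) < target and attempts < 20 * n_background:
            attempts += 1
            i, j = rng.integers(0, len(genes), size=2)
            u, v = genes[i], genes[j]
            if u == v or u in hub_set or v in hub_set:
                continue
            # cap keeps every background node safely below the hub filter
            if degree[u] >= max_background_degree or degree[v] >= max_background_degree:
                continue
            e = tuple(sorted((u, v)))
            if e in edges:
                continue
            edges.add(e)
            degree[u] += 1
            degree[v] += 1
        rows = pd.DataFrame(sorted(edges), columns=["id_a", "id_b"])
        return rows, hub_genes

    phys_a, hubs_a = physical_for(genes_a, plant_hubs=True)
    phys_b, _ = physical_for(genes_b, plant_hubs=False)

    n_disease = round(disease_fraction * len(genes_b))
    diseased = sorted(rng.permutation(genes_b)[:n_disease])
    terms = [f"synthetic_disease_{i:03d}" for i in range(n_disease_terms)]
    disease_rows = []
    for g in diseased:
        for t in rng.choice(n_disease_terms, size=rng.integers(1, 4), replace=False):
            disease_rows.append({"id_a": g, "id_b": terms[t]})
    disease_df = pd.DataFrame(disease_rows, columns=["id_a", "id_b"])

    tables = {
        "orthologs": PairTable(kind="ortholog", rows=ortho_rows),
        "physical": {
            "a": PairTable(kind="physical", rows=phys_a),
            "b": PairTable(kind="physical", rows=phys_b),
        },
        "disease": PairTable(kind="disease", rows=disease_df),
    }
    truth = SyntheticTruth(
        seed=seed,
        planted={
            "hubs": hubs_a,
            "hub_degree": hub_degree,
            "ortholog_pairs": ortho_rows[["id_a", "id_b"]].to_records(index=False).tolist(),
            "disease_genes": diseased,
        },
    )
    return tables, truth


def write_fixture(out_dir: str | Path, seed: int = 0, n_transcripts: int = 2000,
                  n_promoters: int = 100) -> dict[str, str]:
    """Generate a complete on-disk fixture directory: expression TSVs for the
    two synthetic species, genome FASTA + GTF for each, ortholog/physical/
    disease TSVs and a ground-truth JSON.  Returns {artifact: path}."""
    from tisspec.io_formats import write_fasta

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    sub = lambda: int(rng.integers(0, 2**31 - 1))  # noqa: E731

    paths: dict[str, str] = {}
    truths: dict[str, dict] = {}
    plans = {
        "human": {"testis": (50, 100.0), "brain": (30, 100.0), "adipose": (10, 100.0)},
        "fly": {"testis": (60, 100.0), "brain": (20, 100.0), "adipose": (10, 100.0)},
    }
    gene_lists: dict[str, list[str]] = {}
    testis_genes_fly: list[str] = []
    for species in ("human", "fly"):
        expr, truth = gen_expression(
            n_transcripts=n_transcripts, species=species, plan=plans[species], seed=sub()
        )
        p = out / f"expression_{species}.tsv"
        table = expr.values.copy()
        table.insert(0, "gene_id", expr.meta["gene_id"])
        table.insert(1, "exon_count", expr.meta["exon_count"])
        table.insert(2, "biotype", expr.meta["biotype"])
        table.to_csv(p, sep="\t", index_label="transcript_id")
        paths[f"expression_{species}"] = str(p)
        truths[f"expression_{species}"] = asdict(truth)
        gene_lists[species] = sorted(expr.meta["gene_id"].unique())
        if species == "fly":
            testis_genes_fly = sorted(
                expr.meta.loc[truth.planted["enriched"]["testis"], "gene_id"].unique()
            )

        # promoters: every planted enriched transcript, topped up with controls
        planted_ids = sorted(set().union(*truth.planted["enriched"].values()))
        others = [t for t in expr.values.index if t not in set(planted_ids)]
        prom_ids = (planted_ids + others)[: max(n_promoters, len(planted_ids))]
        prom_genes = expr.meta.loc[prom_ids, "gene_id"].tolist()
        genome, gtf_text, gtruth = gen_genome_annotation(
            n_transcripts=len(prom_ids),
            species=species,
            seed=sub(),
            chrom=f"chr{species[0].upper()}1",
            transcript_ids=prom_ids,
            gene_ids=prom_genes,
        )
        fasta_p = out / f"genome_{species}.fasta"
        write_fasta(genome, fasta_p)
        gtf_p = out / f"annotation_{species}.gtf"
        gtf_p.write_text(gtf_text)
        paths[f"genome_{species}"] = str(fasta_p)
        paths[f"annotation_{species}"] = str(gtf_p)
        truths[f"genome_{species}"] = asdict(gtruth)

    tables, ltruth = gen_links(
        gene_lists["fly"],
        gene_lists["human"],
        seed=sub(),
        hub_universe=testis_genes_fly,
    )
    for name, table in (
        ("orthologs", tables["orthologs"]),
        ("physical_fly", tables["physical"]["a"]),
        ("physical_human", tables["physical"]["b"]),
        ("disease", tables["disease"]),
    ):
        p = out / f"{name}.tsv"
        table.rows.to_csv(p, sep="\t", index=False)
        paths[name] = str(p)
    truths["links"] = asdict(ltruth)

    truth_path = out / "truth.json"
    truth_path.write_text(json.dumps(truths, indent=1, sort_keys=True, default=str))
    paths["truth"] = str(truth_path)
    return paths
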