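"""End-to-end orchestration: ingest -> specificity -> categories -> cohort
statistics -> orthology -> network -> TSS profiles -> exports, driven by one
YAML config, with a machine-readable run manifest."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

import tisspec
from tisspec import io_formats, specificity as spc
from tisspec import cohort_stats, network, orthology, tss_profile

logger = logging.getLogger(__name__)

STAGES = (
    "ingest",
    "specificity",
    "categories",
    "cohort_stats",
    "orthology",
    "network",
    "tss_profile",
)


@dataclass
class RunConfig:
    """All inputs, thresholds and window sizes of one analysis run.

    Threshold defaults are the analysis constants: category boundaries
    -0.20 / 0.00 / 0.80, high-enrichment cutoff 0.8, ortholog support >= 12,
    hub degree > 20, expression filter 5, TSS windows 5000/5000 and motif
    windows 300/100/100.
    """

    expression: dict = field(default_factory=dict)  # species -> TSV path
    replicate_groups: dict = field(default_factory=dict)  # species -> {tissue: [cols]}
    annotation: dict = field(default_factory=dict)  # species -> GTF path
    genome: dict = field(default_factory=dict)  # species -> FASTA path
    orthologs: str | None = None
    physical: dict = field(default_factory=dict)  # species -> TSV path
    disease: str | None = None
    species_pair: list = field(default_factory=lambda: ["fly", "human"])
    focal_tissues: list = field(default_factory=lambda: ["brain", "adipose", "testis"])
    category_thresholds: list = field(default_factory=lambda: [-0.20, 0.00, 0.80])
    enrichment_threshold: float = 0.8
    min_ortholog_score: int = 12
    hub_min_degree: int = 20
    expression_filter: float = 5
    apply_expression_filter: bool = False
    normalization_scope: str = "column"
    tss_upstream: int = 5000
    tss_downstream: int = 5000
    seed: int = 0
    output_dir: str = "tisspec_out"
    stages: list = field(default_factory=lambda: list(STAGES))
    plotting: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def validate_paths(self) -> None:
        paths = [
            *self.expression.values(),
            *self.annotation.values(),
            *self.genome.values(),
            *self.physical.values(),
        ]
        if self.orthologs:
            paths.append(self.orthologs)
        if self.disease:
            paths.append(self.disease)
        missing = [p for p in paths if not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"missing input files: {missing}")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; return the manifest dict.

    Deterministic given config + inputs: identical reruns produce
    byte-identical TSV outputs.  Any stage failure aborts with the stage name
    in the raised error.
    """
    config.validate_paths()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "tisspec",
        "version": tisspec.__version__,
        "config_hash": config.config_hash(),
        "stages": {},
        "files": [],
    }
    state: dict = {}

    def record(stage: str, **counts) -> None:
        manifest["stages"][stage] = {"status": "complete", **counts}

    def save(df: pd.DataFrame, name: str, **kw) -> None:
        path = out / name
        df.to_csv(path, sep="\t", **kw)
        manifest["files"].append(name)

    for stage in config.stages:
        try:
            if stage == "ingest":
                state["expr"] = {}
                for species, path in config.expression.items():
                    expr = io_formats.read_expression_table(
                        path,
                        replicate_groups=config.replicate_groups.get(species),
                        species=species,
                    )
                    if config.apply_expression_filter:
                        expr = spc.filter_by_expression(expr, config.expression_filter)
                    state["expr"][species] = expr
                record(stage, **{f"transcripts_{s}": len(e.values) for s, e in state["expr"].items()})

            elif stage == "specificity":
                state["spec"] = {
                    s: spc.compute_specificity(e, scope=config.normalization_scope)
                    for s, e in state["expr"].items()
                }
                for s, spec in state["spec"].items():
                    save(spec.normalized.round(6), f"specificity_{s}.tsv", index_label="transcript_id")
                record(stage, species=len(state["spec"]))

            elif stage == "categories":
                t = config.category_thresholds
                thresholds = spc.CategoryThresholds(*t)
                state["assign"] = {
                    s: spc.assign_categories(spec, thresholds)
                    for s, spec in state["spec"].items()
                }
                counts = {}
                for s, spec in state["spec"].items():
                    summary = spc.summarize_transcript(spec)
                    assign = state["assign"][s]
                    expr = state["expr"][s]
                    table = pd.concat(
                        [expr.meta[["gene_id"]], summary, assign.add_suffix("_category")],
                        axis=1,
                    )
                    save(table, f"transcript_summary_{s}.tsv", index_label="transcript_id")
                    for tissue in config.focal_tissues:
                        if tissue in spec.normalized.columns:
                            n, frac = spc.count_enriched(spec, tissue, config.enrichment_threshold)
                            counts[f"enriched_{s}_{tissue}"] = n
                record(stage, **counts)

            elif stage == "cohort_stats":
                rows = []
                for s, assign in state["assign"].items():
                    expr = state["expr"][s]
                    spec = state["spec"][s]
                    for tissue in config.focal_tissues:
                        if tissue not in assign.columns:
                            continue
                        gs = cohort_stats.group_summary(assign, expr, tissue)
                        gs.insert(0, "tissue", tissue)
                        gs.insert(0, "species", s)
                        rows.append(gs.reset_index())
                        tests = cohort_stats.pairwise_category_tests(
                            assign, expr.values[tissue], tissue
                        )
                        tests.insert(0, "tissue", tissue)
                        tests.insert(0, "species", s)
                        rows_t = tests
                        save(rows_t, f"welch_{s}_{tissue}.tsv", index=False)
                    # correlation features per species over focal tissues
                    feats = {"maxexp": expr.values.max(axis=1)}
                    for tissue in config.focal_tissues:
                        if tissue in expr.values.columns:
                            feats[f"{tissue}exp"] = expr.values[tissue]
                            feats[f"{tissue}sp"] = spec.normalized[tissue]
                    feats["exon"] = expr.meta["exon_count"]
                    feats["transcriptn"] = expr.meta.groupby("gene_id")["gene_id"].transform("size")
                    cm = cohort_stats.correlation_matrix(pd.DataFrame(feats))
                    save(cm.coefficients.round(4), f"correlation_{s}.tsv")
                if rows:
                    save(pd.concat(rows, ignore_index=True), "group_summaries.tsv", index=False)
                record(stage, summaries=len(rows))

            elif stage == "orthology":
                links = io_formats.read_pair_table(config.orthologs, "ortholog")
                links = orthology.filter_orthologs(links, config.min_ortholog_score)
                state["links"] = links
                sp_a, sp_b = config.species_pair
                state["gene_sets"] = {
                    s: orthology.highly_enriched_gene_sets(
                        state["assign"][s], state["expr"][s].meta, config.focal_tissues
                    )
                    for s in (sp_a, sp_b)
                }
                counts = {"ortholog_links": len(links.rows)}
                for tissue in config.focal_tissues:
                    sum_a = orthology.gene_level_summary(
                        state["spec"][sp_a], state["expr"][sp_a], tissue
                    )
                    sum_b = orthology.gene_level_summary(
                        state["spec"][sp_b], state["expr"][sp_b], tissue
                    )
                    joined = orthology.join_cross_species(sum_a, sum_b, links)
                    save(joined.round(6), f"ortholog_joined_{tissue}.tsv", index=False)
                    counts[f"joined_{tissue}"] = len(joined)
                # Venn of genes with highly enriched transcripts (ortholog universe)
                for s in (sp_a, sp_b):
                    linked = set(links.rows["id_a" if s == sp_a else "id_b"])
                    sets = {
                        t: state["gene_sets"][s][t] & linked for t in config.focal_tissues
                    }
                    if len(sets) in (2, 3):
                        venn = orthology.venn_overlap(sets)
                        save(venn.to_frame(), f"venn_{s}.tsv", index=False)
                if config.disease:
                    disease = io_formats.read_pair_table(config.disease, "disease")
                    drows = []
                    for tissue in config.focal_tissues:
                        linked_b = set(links.rows["id_b"])
                        gene_set = state["gene_sets"][sp_b][tissue] & linked_b
                        ds = orthology.disease_summary(gene_set, disease)
                        drows.append(
                            {
                                "tissue": tissue,
                                "gene_set_size": ds.gene_set_size,
                                "disease_associated": ds.associated_count,
                                "percentage": ds.percentage,
                            }
                        )
                        counts[f"disease_pct_{tissue}"] = ds.percentage
                    save(pd.DataFrame(drows), "disease_summary.tsv", index=False)
                record(stage, **counts)

            elif stage == "network":
                sp_a, sp_b = config.species_pair
                physical = {
                    s: io_formats.read_pair_table(p, "physical")
                    for s, p in config.physical.items()
                }
                graph = network.build_network(
                    state["gene_sets"], physical, state["links"], species_pair=(sp_a, sp_b)
                )
                table = network.centrality(graph)
                hubs = network.filter_hubs(graph, table, config.hub_min_degree)
                edges, nodes = network.export_tables(graph, table)
                save(edges, "network_edges.tsv", index=False)
                save(nodes, "network_nodes.tsv", index=False)
                network.write_graphml(graph, out / "network.graphml")
                manifest["files"].append("network.graphml")
                counts = {
                    "nodes": graph.number_of_nodes(),
                    "edges": graph.number_of_edges(),
                    "hubs": hubs.number_of_nodes(),
                }
                for tissue in config.focal_tissues:
                    try:
                        sub = network.ortholog_pair_subnetwork(graph, tissue)
                        counts[f"ortholog_subnet_{tissue}"] = sub.number_of_nodes()
                    except KeyError:
                        counts[f"ortholog_subnet_{tissue}"] = 0
                state["graph"] = graph
                record(stage, **counts)

            elif stage == "tss_profile":
                counts = {}
                for s, gtf_path in config.annotation.items():
                    genome = io_formats.read_fasta(config.genome[s])
                    anns = io_formats.read_annotation(gtf_path, "gtf")
                    recs = {r.transcript_id: r for r in tss_profile.tss_coordinates(anns)}
                    spec = state["spec"].get(s)
                    U, D = config.tss_upstream, config.tss_downstream
                    profiles = {}
                    # control: transcripts never highly enriched anywhere
                    if spec is not None:
                        ctrl_ids = set(tss_profile.control_set(spec, config.enrichment_threshold))
                    else:
                        ctrl_ids = set(recs)
                    ctrl_recs = [r for tid, r in recs.items() if tid in ctrl_ids]
                    if ctrl_recs:
                        flanks = tss_profile.extract_flanks(genome, ctrl_recs, U, D)
                        profiles["control"] = tss_profile.base_profile(flanks)
                        counts[f"control_seqs_{s}"] = len(flanks.sequences)
                    enriched_any: set[str] = set()
                    if spec is not None and "assign" in state:
                        for tissue in config.focal_tissues:
                            if tissue not in state["assign"][s].columns:
                                continue
                            assign = state["assign"][s]
                            ids = set(assign.index[assign[tissue] == "highly_enriched"])
                            enriched_any |= ids
                            trecs = [r for tid, r in recs.items() if tid in ids]
                            if trecs:
                                flanks = tss_profile.extract_flanks(genome, trecs, U, D)
                                profiles[tissue] = tss_profile.base_profile(flanks)
                                counts[f"tss_seqs_{s}_{tissue}"] = len(flanks.sequences)
                    for name, prof in profiles.items():
                        save(
                            tss_profile.profile_to_frame(prof).round(6),
                            f"profile_{s}_{name}.tsv",
                            index=False,
                        )
                    if "control" in profiles:
                        comp_rows = []
                        for name, prof in profiles.items():
                            if name == "control":
                                continue
                            dist = tss_profile.profile_distance(prof, profiles["control"])
                            corr = tss_profile.profile_correlation(prof, profiles["control"])
                            comp_rows.append(
                                {
                                    "set": name,
                                    "mse": dist["mse"],
                                    "euclidean": dist["euclidean"],
                                    "pearson_pooled": corr["pooled"],
                                }
                            )
                        if comp_rows:
                            save(pd.DataFrame(comp_rows), f"profile_vs_control_{s}.tsv", index=False)
                    # motif windows: targets = highly enriched in any focal tissue,
                    # background = genes lacking highly enriched variants
                    target_recs = [r for tid, r in recs.items() if tid in enriched_any]
                    bg_recs = [r for tid, r in recs.items() if tid in ctrl_ids]
                    if target_recs and bg_recs:
                        written = tss_profile.export_motif_windows(
                            genome, target_recs, bg_recs, out / f"motif_{s}"
                        )
                        manifest["files"].extend(
                            str(Path(p).relative_to(out)) for p in written.values()
                        )
                record(stage, **counts)
            else:
                raise ValueError(f"unknown stage {stage!r}")
        except Exception as exc:
            manifest["stages"][stage] = {"status": "failed", "error": str(exc)}
            (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def report_summary(output_dir: str | Path, plotting: bool = False) -> str:
    """Human-readable report over a completed run's output directory."""
    out = Path(output_dir)
    manifest_path = out / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest.json in {out}; run the pipeline first")
    manifest = json.loads(manifest_path.read_text())
    lines = [
        f"tisspec {manifest.get('version', '?')} run report",
        f"config hash: {manifest.get('config_hash', '?')}",
        "",
        "stages:",
    ]
    for stage, info in manifest.get("stages", {}).items():
        lines.append(f"  {stage}: {info.get('status')}")
        for k, v in info.items():
            if k != "status":
                lines.append(f"    {k}: {v}")
    summaries = out / "group_summaries.tsv"
    if summaries.exists():
        df = pd.read_csv(summaries, sep="\t")
        lines += ["", "category counts per tissue:"]
        pivot = df.pivot_table(
            index=["species", "tissue"], columns="category",
            values="transcript_count", aggfunc="first",
        )
        lines.append(pivot.to_string())
    else:
        lines += ["", "no focal tissues summarized"]
    for venn_file in sorted(out.glob("venn_*.tsv")):
        lines += ["", f"{venn_file.name}:", pd.read_csv(venn_file, sep="\t").to_string(index=False)]
    nodes = out / "network_nodes.tsv"
    if nodes.exists():
        df = pd.read_csv(nodes, sep="\t")
        hubs = df[df["degree"] > 20]
        lines += ["", f"hub nodes (degree > 20): {len(hubs)}"]
        if len(hubs):
            lines.append(hubs[["node", "degree"]].to_string(index=False))
    if plotting:
        made = render_profile_plots(out)
        lines += ["", f"profile plots: {', '.join(made) if made else 'none'}"]
    report = "\n".join(lines) + "\n"
    (out / "report.txt").write_text(report)
    return report


def render_profile_plots(out_dir: str | Path) -> list[str]:
    """Render per-position base-frequency line plots for every profile TSV."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    made = []
    for tsv in sorted(out.glob("profile_*.tsv")):
        df = pd.read_csv(tsv, sep="\t")
        fig, ax = plt.subplots(figsize=(8, 3))
        for base in "ATGC":
            ax.plot(df["position"], df[base], label=base, linewidth=0.8)
        ax.set_xlabel("position relative to TSS")
        ax.set_ylabel("frequency")
        ax.legend(ncol=4, fontsize=8)
        ax.set_title(tsv.stem)
        png = tsv.with_suffix(".png")
        fig.tight_layout()
        fig.savefig(png, dpi=100)
        plt.close(fig)
        made.append(png.name)
    return made
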