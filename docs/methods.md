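# Methods

## The specificity statistic

For each transcript, expression values e₁…eₙ over the n tissues of one
species are standardized per row:

x_i = (e_i − ē) / s, with s the sample standard deviation (ddof = 1).

Properties that shape everything downstream:

- The statistic is scale-free per transcript (a transcript-wide
  multiplicative factor cancels), so FPKM vs TPM units do not matter.
- A transcript expressed in exactly one tissue reaches the ceiling
  (n−1)/√n, regardless of magnitude; for the 33-tissue panel that is
  5.5705, for the 17-tissue panel 3.8806. Tests check this closed form
  against direct formula evaluation.
- Rows with zero variance (all-equal, including all-zero) are defined as 0
  everywhere: such transcripts are maximally non-specific, and the
  definition avoids 0/0.

Raw indices are scaled into [−1, 1] by max-abs scaling. The default scope
is per tissue column — each tissue's most extreme transcript sits at ±1 —
which matches feature-wise max-abs scaling of a transcripts × tissues
matrix; a `global` scope (one divisor for the whole matrix) is available as
a flag because the choice is analytically consequential: per-column scaling
makes normalized values comparable *within* a tissue, global scaling
*across* tissues.

Categories on the normalized value x: underrepresented (x < −0.20),
general (−0.20 ≤ x ≤ 0), enriched (0 < x ≤ 0.80), highly enriched
(x > 0.80). Boundary inclusivity mirrors the wording of the category
definitions ("below", "between", "from 0 to 0.80", "exceeding"); the four
categories partition every cell, which is a tested invariant.

Tissue-exclusion re-analysis (`exclude_tissues_recompute`) recomputes the
whole statistic on the column subset, so n in the formula — and hence the
attainable ceiling — shrinks with the panel. The expression filter keeps
transcripts whose *maximum* expression across tissues is ≥ 5; the maximum
(rather than the mean) removes globally weak transcripts without penalizing
tissue-restricted ones.

## Cohort statistics

Per-category summaries report gene/transcript counts, mean and median
tissue and maximum expression, exon counts, and median transcripts per
gene. 95% confidence intervals use the t-distribution,
t₀.₉₇₅,ₘ₋₁·s/√m; singleton groups get no CI and empty categories get
absent (NaN) statistics rather than zeros. Between-category location tests
are Welch's two-tailed t-test (Welch–Satterthwaite df), reported
uncorrected for multiplicity with the conventional star scheme
(*/**/*** at 0.05/0.01/0.001); all C(4,2) category pairs are tested since
the choice of comparison pairs is a presentation decision, not a
statistical one. Correlation matrices use pairwise-complete observations
(≥ 3 per pair), default to Spearman whenever a feature is an expression or
specificity vector, use average ranks for ties, and flag constant vectors
as absent coefficients instead of 0.

## Orthology and networks

Ortholog links carry an integer database-support count (1–15); the default
filter keeps pairs supported by at least 12 databases (inclusive cutoff;
the threshold is a parameter). Gene-level values for the cross-species
join are taken from the gene's transcript with maximal normalized
specificity in the focal tissue — this preserves the enrichment signal the
analysis tracks; mean aggregation is available as a flag. Many-to-many
links produce one joined row per pair; links with a missing partner are
dropped and counted in the log.

Venn decompositions of 2–3 gene sets are exact region partitions (region
counts provably sum to the union; tested against brute-force membership
enumeration). Disease summaries count a gene once regardless of its number
of disease annotations and round percentages half-up to one decimal, the
convention used when such tables are printed.

The cross-species graph types its edges: `physical` edges connect genes of
the same species, `ortholog` edges connect species. Nodes are the union of
per-tissue highly-enriched gene sets; physical edges are kept only between
present nodes. Centralities are computed on the physical subgraph only —
ortholog edges never contribute to shortest paths — per connected
component: betweenness normalized by (m−1)(m−2)/2 for component size m,
closeness (m−1)/Σd with isolated nodes scored 0 (per-component harmonic
closeness is an option). The hub filter is strict (degree > 20; degree
exactly 20 is dropped). Degree is computed on the built (tissue-restricted)
graph, and that restriction is deliberate: it asks which genes are hubs
*within the enriched sets*, not in the global interactome.

## TSS profiles

The TSS of a transcript is its first transcribed base: annotation start on
the + strand, end − 1 (0-based half-open internally) on the − strand.
Flanks of length U + D are oriented to the transcript strand
(− strand windows are reverse-complemented), so "upstream" always means 5′
— the downstream T/G skew only appears under strand-aware extraction, which
is tested by ablation. Windows running off a contig are N-padded; N never
enters a frequency denominator. Default profile window U = D = 5000 (a
10 kb view); motif-export windows are upstream 300, upstream 100 and
downstream 100 bp.

Flank sets are deduplicated by exact uppercased string — identical
annotated TSSs of transcript variants collapse automatically — keeping
first-seen order and collapse counts. Profiles are per-position A/T/G/C
frequencies among non-N observations; smoothing (centered moving average)
exists for plotting parity but is off by default. Profile comparisons
report MSE and Euclidean distance on concatenated per-base frequency
vectors plus per-base components, and per-base Pearson (or Spearman)
correlations over selectable sub-windows (defaults: upstream
[−5000, −500), TSS-centered [−500, +500), full), labeled with the range
used. The control set contains transcripts never highly enriched in any
tissue of their species; the motif background is the stricter gene-level
version (genes lacking any highly enriched variant). Non-coding TSS sets
smaller than 50 sequences are refused rather than profiled, since such
profiles are dominated by noise.

## Synthetic data: what it emulates and what it does not

The generators produce every input the pipeline consumes, with ground
truth, under a single explicit seed each (no global RNG state):

- **Expression**: log-normal background (default meanlog 1.0, sdlog 1.0 —
  right-skewed like atlas FPKM/TPM), 33 tissues human-like / 17 fly-like,
  transcripts-per-gene means 3.4 and 2.2 respectively, Poisson-derived
  exon counts (means 8 and 4), 25% non-coding. Planting: a planned tissue
  gets its transcript's value raised to fold × max(own draw, background
  median), so "fold over background" holds for every planted transcript
  regardless of its own background draw. With fold 100 the planted row is
  dominated by one tissue and lands at the specificity ceiling.
- **Genomes**: i.i.d. background at 42% GC; per transcript, the promoter
  window carries a GC rise (+0.15 G+C over [−100, 0)), an AT peak (+0.20
  A+T at −25 ± 5) and a downstream T and G excess (+0.05 each over 500
  bases), planted on the transcript strand; about half the transcripts are
  on the − strand. Transcripts occupy non-overlapping slots (overlap is
  refused, keeping planted windows independent).
- **Links**: scored ortholog pairs; physical edges with 5 designated hubs
  of exact degree 25 and a random background capped at per-node degree 10
  (non-hub nodes can reach at most 10 + one edge per hub = 15 < 20, so the
  strict degree filter provably isolates exactly the planted hubs);
  disease terms on a configurable fraction of genes.

What passing recovery tests shows — and does not. The background has no
tissue factors, batch structure, or expression-dependent noise, and planted
signals are step functions, not graded enrichment. Recovery of planted
fold-100 transcripts therefore demonstrates that the statistic, the
normalization and the thresholds are wired correctly, not that 0.8 is the
right threshold for real atlases. One behavior of the statistic is worth
stating explicitly because the synthetic null exposes it: with any
right-skewed background, a substantial fraction of transcripts (roughly
6–20% across plausible noise levels, measured by their maximum normalized
specificity over tissues) exceeds 0.8 somewhere, because a row with one
dominant draw approaches the (n−1)/√n ceiling regardless of magnitude.
This is intrinsic to standardized-expression indices on heavy-tailed data
— real atlases show the same order of magnitude — so the generator's
false-positive budget (< 1% at fold 1) is defined and tested per focal
tissue, which is also the measure the fold-100 recovery experiment uses.

## Numerical choices and degenerate inputs

- Internal coordinates are 0-based half-open everywhere; GTF (1-based
  closed) is converted at the I/O boundary only.
- Missing expression cells ingest as 0 with a logged count.
- Argmax ties break lexicographically by tissue name for reproducibility.
- Welch's test refuses two zero-variance samples (undefined statistic);
  correlation refuses pairs with < 3 complete observations.
- Frequency sums are validated to 1 ± 1e−9 at covered positions; profile
  distances treat all-N positions as pairwise missing.
- All percentages intended for tables round half-up (decimal arithmetic,
  not banker's rounding).

## Problem sizes

Tests and the acceptance script run at desk scale: 2000-transcript
matrices for enrichment recovery, 500 promoters for composition recovery,
200-gene universes for hub retention, ≤ 50-node graphs for the centrality
oracle. These sizes were chosen so the planted effects are measured with
comfortable statistical margins while the whole suite stays fast.

## Known limitations

- No gene-level specificity statistic (τ and relatives are out of scope).
- Ortholog links are consumed, never inferred.
- Motif discovery is delegated to external tools; the package guarantees
  byte-stable input FASTA only.
- The "tissue-specific" end of the scale (values near 1) has no fixed
  cutoff; the enrichment threshold is a parameter everywhere.
- Whether normalization should be per tissue column or global is exposed
  as an option because both are defensible; results depend on the choice.
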