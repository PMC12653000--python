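"""Strand-aware TSS flank extraction, base profiles, control sets and
profile comparison."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from tisspec.io_formats import TranscriptAnnotation, read_fasta
from tisspec.specificity import SpecificityMatrix
from tisspec.tss_profile import (
    BaseProfile,
    TSSRecord,
    base_profile,
    control_gene_background,
    control_set,
    dedup_sequences,
    export_motif_windows,
    extract_flank,
    extract_flanks,
    profile_correlation,
    profile_distance,
    reverse_complement,
    select_noncoding,
    tss_coordinates,
)


def norm_spec(values, tissues=("brain", "testis")):
    df = pd.DataFrame(values, columns=list(tissues))
    df.index = [f"t{i}" for i in range(len(df))]
    return SpecificityMatrix(raw=df, normalized=df)


class TestTSSCoordinates:
    def test_plus_strand(self):
        a = TranscriptAnnotation("t1", "c1", 99, 200, "+", "g1")
        (rec,) = tss_coordinates([a])
        assert rec.tss == 99

    def test_minus_strand(self):
        a = TranscriptAnnotation("t1", "c1", 99, 200, "-", "g1")
        (rec,) = tss_coordinates([a])
        assert rec.tss == 199

    def test_missing_strand_rejected_at_construction(self):
        with pytest.raises(ValueError):
            TranscriptAnnotation("t1", "c1", 99, 200, ".", "g1")


class TestExtractFlank:
    def test_plus_strand_slice(self, toy_genome):
        rec = TSSRecord("t", "c1", 2, "+")
        assert extract_flank(toy_genome, rec, 2, 3) == "ACGTA"

    def test_minus_strand_revcomp(self, toy_genome):
        rec = TSSRecord("t", "c1", 5, "-")
        seq = extract_flank(toy_genome, rec, 2, 3)
        assert seq == "ACGTA"
        assert seq[2] == "G"  # complement of the C at genomic position 5

    def test_left_padding(self, toy_genome):
        rec = TSSRecord("t", "c1", 1, "+")
        assert extract_flank(toy_genome, rec, 3, 2) == "NNACG"

    def test_right_padding_minus_strand(self, toy_genome):
        rec = TSSRecord("t", "c1", 8, "-")
        # genomic slice [6, 12) runs off the 10-base contig
        seq = extract_flank(toy_genome, rec, 3, 3)
        assert len(seq) == 6
        assert seq.startswith("NN") or seq.endswith("NN") or "N" in seq

    def test_unknown_chrom(self, toy_genome):
        with pytest.raises(KeyError):
            extract_flank(toy_genome, TSSRecord("t", "cX", 2, "+"), 1, 1)

    @settings(max_examples=50, deadline=None)
    @given(
        genome=st.text(alphabet="ACGT", min_size=20, max_size=80),
        tss=st.integers(5, 15),
        u=st.integers(1, 8),
        d=st.integers(1, 8),
    )
    def test_strand_round_trip(self, genome, tss, u, d):
        """+ strand flank equals the - strand flank at the mirrored TSS of the
        reverse-complemented genome."""
        fwd = extract_flank({"c": genome}, TSSRecord("t", "c", tss, "+"), u, d)
        mirror = len(genome) - 1 - tss
        rev = extract_flank(
            {"c": reverse_complement(genome)}, TSSRecord("t", "c", mirror, "-"), u, d
        )
        assert fwd == rev


class TestDedup:
    def test_case_fold_collapse(self):
        fs = dedup_sequences(["ACGT", "acgt", "AAAA"])
        assert fs.sequences == ["ACGT", "AAAA"]
        assert fs.counts == [2, 1]

    def test_all_distinct_identity(self):
        fs = dedup_sequences(["AC", "GT"])
        assert fs.sequences == ["AC", "GT"]

    def test_empty(self):
        assert dedup_sequences([]).sequences == []

    def test_mixed_lengths_rejected(self):
        with pytest.raises(ValueError):
            dedup_sequences(["AC", "ACG"])


class TestBaseProfile:
    def test_single_sequence_indicators(self):
        fs = dedup_sequences(["ACGT"])
        prof = base_profile(fs)
        assert prof.frequencies.iloc[0]["A"] == 1.0
        assert prof.frequencies.iloc[1]["C"] == 1.0

    def test_n_excluded_from_denominator(self):
        fs = dedup_sequences(["AAAA", "AAAN"])
        prof = base_profile(fs)
        assert prof.frequencies.iloc[-1]["A"] == 1.0
        assert prof.counts.iloc[-1] == 1

    def test_symmetric_pair(self):
        prof = base_profile(dedup_sequences(["AT", "TA"]))
        assert (prof.frequencies["A"] == 0.5).all()
        assert (prof.frequencies["T"] == 0.5).all()

    def test_frequencies_sum_to_one_and_counts_match(self):
        rng = np.random.default_rng(3)
        seqs = [
            "".join(rng.choice(list("ACGTN"), size=30)) for _ in range(40)
        ]
        fs = dedup_sequences(seqs)
        prof = base_profile(fs)
        sums = prof.frequencies.sum(axis=1)
        covered = prof.counts > 0
        assert sums[covered].to_numpy() == pytest.approx(1.0, abs=1e-9)
        n_chars = sum(s.count("N") for s in fs.sequences)
        assert prof.counts.sum() == sum(len(s) for s in fs.sequences) - n_chars

    def test_empty_rejected(self):
        from tisspec.tss_profile import FlankSet

        with pytest.raises(ValueError):
            base_profile(FlankSet(0, 0, [], []))

    def test_positions_centered_on_tss(self):
        fs = extract_flanks({"c": "ACGTACGTAC"}, [TSSRecord("t", "c", 5, "+")], 2, 3)
        prof = base_profile(fs)
        assert prof.positions.tolist() == [-2, -1, 0, 1, 2]


class TestControlSets:
    def test_threshold_inclusion(self):
        spec = norm_spec([[0.5, 0.3], [0.85, 0.2], [0.8, 0.8]])
        assert control_set(spec) == ["t0", "t2"]

    def test_threshold_one_includes_all(self):
        spec = norm_spec([[0.5, 0.3], [0.85, 0.2]])
        assert control_set(spec, 1.0) == ["t0", "t1"]

    def test_gene_background_excludes_whole_gene(self):
        spec = norm_spec([[0.9, 0.1], [0.1, 0.1], [0.2, 0.2]])
        meta = pd.DataFrame(
            {"gene_id": ["g0", "g0", "g1"]}, index=["t0", "t1", "t2"]
        )
        # t1 itself is low but shares g0 with the enriched t0
        assert control_gene_background(spec, meta) == ["t2"]


class TestSelectNoncoding:
    def ann(self, i, biotype):
        return TranscriptAnnotation(f"t{i}", "c", 100 * i + 1, 100 * i + 50, "+", f"g{i}", biotype)

    def test_partition_and_guard(self):
        anns = [self.ann(i, "noncoding") for i in range(70)] + [
            self.ann(i + 100, "coding") for i in range(10)
        ]
        enriched = {f"t{i}" for i in range(60)}
        rep = select_noncoding(anns, enriched, min_set_size=50)
        assert rep["enriched"]["profiled"] and rep["enriched"]["n"] == 60
        assert not rep["other"]["profiled"] and "too few" in rep["other"]["note"]

    def test_no_noncoding(self):
        anns = [self.ann(i, "coding") for i in range(5)]
        rep = select_noncoding(anns, set())
        assert rep["enriched"]["n"] == 0 and rep["other"]["n"] == 0


def make_profile(mat, start):
    df = pd.DataFrame(mat, columns=list("ATGC"))
    df.index = pd.Index(range(start, start + len(df)), name="position")
    return BaseProfile(frequencies=df, counts=pd.Series(10, index=df.index))


class TestProfileComparison:
    def test_distance_zero_iff_equal(self):
        p = make_profile([[0.25, 0.25, 0.25, 0.25]] * 4, -2)
        d = profile_distance(p, p)
        assert d["mse"] == 0 and d["euclidean"] == 0
        q = make_profile([[0.25, 0.25, 0.25, 0.25]] * 3 + [[0.4, 0.1, 0.25, 0.25]], -2)
        assert profile_distance(p, q)["mse"] > 0

    def test_hand_computed_vectors(self):
        # per-base vectors (0,1) vs (1,1): MSE 0.5, Euclidean 1.0
        p = make_profile([[0, 1, 0, 0], [1, 0, 0, 0]], 0)
        q = make_profile([[1, 1, 0, 0], [1, 0, 0, 0]], 0)
        d = profile_distance(p, q)
        assert d["per_base"]["A"]["mse"] == pytest.approx(0.5)
        assert d["per_base"]["A"]["euclidean"] == pytest.approx(1.0)

    def test_mismatched_ranges_rejected(self):
        p = make_profile([[1, 0, 0, 0]] * 3, 0)
        q = make_profile([[1, 0, 0, 0]] * 3, 1)
        with pytest.raises(ValueError):
            profile_distance(p, q)

    def test_self_correlation_unity(self):
        rng = np.random.default_rng(0)
        mat = rng.dirichlet(np.ones(4), size=20)
        p = make_profile(mat, -10)
        corr = profile_correlation(p, p)
        for b in "ATGC":
            assert corr["per_base"][b] == pytest.approx(1.0)
        assert corr["pooled"] == pytest.approx(1.0)

    def test_window_restriction_detects_divergence(self):
        """Two profiles identical upstream, divergent downstream: the upstream
        window correlates higher than the downstream window."""
        rng = np.random.default_rng(5)
        up = rng.dirichlet(np.ones(4), size=20)
        down_p = rng.dirichlet(np.ones(4), size=20)
        down_q = rng.dirichlet(np.ones(4), size=20)
        p = make_profile(np.vstack([up, down_p]), -20)
        q = make_profile(np.vstack([up, down_q]), -20)
        up_corr = profile_correlation(p, q, window=(-20, 0))["pooled"]
        down_corr = profile_correlation(p, q, window=(0, 20))["pooled"]
        assert up_corr == pytest.approx(1.0)
        assert down_corr < up_corr


class TestMotifExport:
    def test_fasta_counts_match_unique_sequences(self, tmp_path):
        rng = np.random.default_rng(2)
        genome = {"c": "".join(rng.choice(list("ACGT"), size=5000))}
        targets = [TSSRecord(f"t{i}", "c", 600 + 40 * i, "+") for i in range(5)]
        background = [TSSRecord(f"b{i}", "c", 2600 + 40 * i, "-") for i in range(7)]
        written = export_motif_windows(genome, targets, background, tmp_path)
        assert set(written) == {
            "target_upstream300", "background_upstream300",
            "target_upstream100", "background_upstream100",
            "target_downstream100", "background_downstream100",
        }
        fa = read_fasta(written["target_upstream300"])
        assert len(fa) == 5
        assert all(len(s) == 300 for s in fa.values())
        fa = read_fasta(written["background_downstream100"])
        assert len(fa) == 7
        assert all(len(s) == 100 for s in fa.values())
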