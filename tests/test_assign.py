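"""Hierarchical category assignment, gene counting, biotype summaries, filters."""

import numpy as np
import pandas as pd
import pytest

from stakit.annotation import AnnotationBundle, TranscriptModel
from stakit.assign import (
    Alignment,
    categorize_read,
    count_categories,
    count_genes,
    filter_summed_counts,
    load_alignments,
    summarize_biotypes,
)
from stakit.intervals import ContractError, GenomicInterval


def iv(start, end, strand="+", chrom="chr1"):
    return GenomicInterval(chrom, start, end, strand)


def aln(start, end, strand="+", rid="r", chrom="chr1"):
    return Alignment(rid, iv(start, end, strand, chrom))


@pytest.fixture()
def layered_bundle():
    """One gene whose exon sits on top of a repeat, plus isolated layers."""
    gene = TranscriptModel(
        "GA", "GA_T", "protein_coding", iv(0, 1000), (iv(0, 200), iv(800, 1000))
    )
    return AnnotationBundle.build(
        [gene],
        trna=[iv(2000, 2072, "+")],
        repeats=[iv(100, 300, "+"), iv(3000, 3300, "+")],
    )


class TestCategorize:
    def test_exon_beats_repeat(self, layered_bundle):
        assert categorize_read(aln(120, 160), layered_bundle) == "exon"

    def test_intron_beats_repeat(self, layered_bundle):
        # (200,300) is intron of GA and also repeat; intron has priority
        assert categorize_read(aln(210, 260), layered_bundle) == "intron"

    def test_isolated_layers(self, layered_bundle):
        assert categorize_read(aln(2010, 2050), layered_bundle) == "trna"
        assert categorize_read(aln(3100, 3150), layered_bundle) == "repeat"
        assert categorize_read(aln(5000, 5050), layered_bundle) == "unannotated"

    def test_antisense_overlap_is_unannotated(self, layered_bundle):
        assert categorize_read(aln(120, 160, "-"), layered_bundle) == "unannotated"
        assert categorize_read(aln(400, 450, "-"), layered_bundle) == "unannotated"

    def test_non_primary_rejected(self, layered_bundle):
        bad = Alignment("r", iv(0, 10), is_primary=False)
        with pytest.raises(ContractError):
            categorize_read(bad, layered_bundle)

    def test_adding_repeat_under_exon_changes_nothing(self, layered_bundle, bundle,
                                                      default_library):
        """Priority dominance on the simulated library."""
        ref_alns = default_library.truth_alignments()
        before = [categorize_read(a, bundle) for a in ref_alns]
        shadowed = AnnotationBundle(
            gene_exons=bundle.gene_exons,
            gene_biotype=bundle.gene_biotype,
            introns=bundle.introns,
            trna=bundle.trna,
            repeats=bundle.repeats
            + [x for ivs in bundle.gene_exons.values() for x in ivs],
            mirna_primary=bundle.mirna_primary,
            mirna_mature=bundle.mirna_mature,
        )
        after = [categorize_read(a, shadowed) for a in ref_alns]
        assert before == after


class TestCountCategories:
    def test_each_read_counted_once(self, layered_bundle):
        reads = [
            aln(120, 160, rid="e"),
            aln(400, 450, rid="i"),
            aln(2010, 2050, rid="t"),
            aln(3100, 3150, rid="p"),
            aln(5000, 5050, rid="u"),
        ]
        counts = count_categories(reads, layered_bundle)
        assert counts.as_dict() == {
            "exon": 1, "intron": 1, "trna": 1, "repeat": 1, "unannotated": 1
        }
        assert counts.aligned_total == 5

    def test_empty_input(self, layered_bundle):
        assert count_categories([], layered_bundle).aligned_total == 0

    def test_conservation_on_fuzzed_input(self, layered_bundle):
        rng = np.random.default_rng(4)
        reads = []
        for k in range(500):
            s = int(rng.integers(0, 6000))
            e = s + int(rng.integers(1, 100))
            reads.append(aln(s, e, "+" if rng.random() < 0.5 else "-", rid=f"r{k}"))
        counts = count_categories(reads, layered_bundle)
        assert counts.aligned_total == len(reads)


class TestCountGenes:
    @pytest.fixture()
    def two_gene_bundle(self):
        a = TranscriptModel("A", "AT", "pc", iv(0, 200), (iv(0, 200),))
        b = TranscriptModel("B", "BT", "pc", iv(150, 400), (iv(150, 400),))
        return AnnotationBundle.build([a, b])

    def test_single_gene_hit(self, two_gene_bundle):
        got = count_genes([aln(10, 50)], two_gene_bundle)
        assert got.counts == {"A": 1, "B": 0}

    def test_read_spanning_two_genes_increments_both(self, two_gene_bundle):
        got = count_genes([aln(140, 260)], two_gene_bundle)
        assert got.counts == {"A": 1, "B": 1}

    def test_antisense_read_not_counted_forward(self, two_gene_bundle):
        got = count_genes([aln(10, 50, "-")], two_gene_bundle)
        assert got.counts == {"A": 0, "B": 0}
        got = count_genes([aln(10, 50, "-")], two_gene_bundle, strand_mode="reverse")
        assert got.counts == {"A": 1, "B": 0}
        got = count_genes([aln(10, 50, "-")], two_gene_bundle, strand_mode="both")
        assert got.counts == {"A": 1, "B": 0}

    def test_matches_all_pairs_oracle(self, two_gene_bundle):
        rng = np.random.default_rng(5)
        genes = {"A": iv(0, 200), "B": iv(150, 400)}
        reads = []
        for k in range(300):
            s = int(rng.integers(0, 450))
            reads.append(aln(s, s + int(rng.integers(1, 80)),
                             "+" if rng.random() < 0.7 else "-", rid=f"r{k}"))
        got = count_genes(reads, two_gene_bundle)
        expect = {g: 0 for g in genes}
        for r in reads:
            for g, giv in genes.items():
                if r.interval.strand == "+" and r.interval.overlap_length(giv) >= 1:
                    expect[g] += 1
        assert got.counts == expect


class TestBiotypeSummary:
    @pytest.fixture()
    def biotype_bundle(self):
        ts = [
            TranscriptModel("P", "PT", "protein_coding", iv(0, 100), (iv(0, 100),)),
            TranscriptModel("S", "ST", "snoRNA", iv(200, 300), (iv(200, 300),)),
            TranscriptModel("M", "MT", "miRNA", iv(400, 500), (iv(400, 500),)),
        ]
        return AnnotationBundle.build(ts)

    def test_proportions(self, biotype_bundle):
        reads = (
            [aln(10, 30, rid=f"p{i}") for i in range(4)]
            + [aln(210, 230, rid=f"s{i}") for i in range(3)]
            + [aln(410, 430, rid=f"m{i}") for i in range(3)]
        )
        summary = summarize_biotypes(reads, biotype_bundle)
        assert summary.exon_total == 10
        assert summary.fractions() == {
            "miRNA": 0.3, "protein_coding": 0.4, "snoRNA": 0.3
        }

    def test_counts_sum_to_exon_total(self, bundle, default_library):
        summary = summarize_biotypes(default_library.truth_alignments(), bundle)
        assert sum(summary.counts.values()) == summary.exon_total

    def test_tie_resolution_largest_overlap_then_gene_id(self):
        ts = [
            TranscriptModel("G1", "T1", "bioA", iv(0, 100), (iv(0, 100),)),
            TranscriptModel("G2", "T2", "bioB", iv(50, 200), (iv(50, 200),)),
        ]
        b = AnnotationBundle.build(ts)
        # overlap 30 with G2, 10 with G1 -> G2 wins
        s = summarize_biotypes([aln(90, 130)], b)
        assert s.counts == {"bioB": 1}
        # equal overlap -> lexicographically smaller gene id wins
        s = summarize_biotypes([aln(40, 110)], b)  # 60 bases in G1, 60 in G2
        assert s.counts == {"bioA": 1}

    def test_empty(self, biotype_bundle):
        s = summarize_biotypes([], biotype_bundle)
        assert s.exon_total == 0 and s.counts == {}


class TestFilterSummedCounts:
    def test_strict_threshold(self):
        m = pd.DataFrame(
            {"lib1": [11, 10, 0], "lib2": [10, 10, 0]}, index=["A", "B", "C"]
        )
        assert list(filter_summed_counts(m, 20).index) == ["A"]  # B sums to exactly 20
        assert list(filter_summed_counts(m, 0).index) == ["A", "B"]

    def test_matches_row_sum_oracle(self):
        rng = np.random.default_rng(6)
        m = pd.DataFrame(rng.integers(0, 100, size=(50, 6)))
        for thr in (0, 20, 100, 500):
            got = filter_summed_counts(m, thr)
            assert list(got.index) == [i for i in m.index if m.loc[i].sum() > thr]


class TestAlignmentInput:
    def test_sam_primary_only(self, tmp_path):
        sam = tmp_path / "a.sam"
        sam.write_text(
            "@HD\tVN:1.6\tSO:coordinate\n"
            "@SQ\tSN:chr1\tLN:10000\n"
            "r1\t0\tchr1\t101\t60\t20M\t*\t0\t0\t" + "A" * 20 + "\t" + "I" * 20 + "\n"
            "r2\t16\tchr1\t201\t60\t20M\t*\t0\t0\t" + "A" * 20 + "\t" + "I" * 20 + "\n"
            "r2\t272\tchr1\t301\t0\t20M\t*\t0\t0\t*\t*\n"  # secondary: skipped
        )
        alns = load_alignments(sam)
        assert len(alns) == 2
        assert alns[0].interval == iv(100, 120, "+")
        assert alns[1].interval == iv(200, 220, "-")

    def test_bed_roundtrip(self, tmp_path, default_library):
        bed = tmp_path / "truth.bed"
        default_library.write_truth_bed(bed)
        alns = load_alignments(bed)
        assert len(alns) == len(default_library.reads)
        assert alns[0].interval == default_library.reads[0].interval
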