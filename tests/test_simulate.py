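"""Simulator: determinism, chemistry controls, insert-length model, truth."""

import numpy as np
import pytest

from stakit.assign import categorize_read
from stakit.qc import gene_body_coverage
from stakit.simulate import (
    SimConfig,
    SimulationError,
    build_toy_reference,
    emit_truth_alignments,
    simulate_library,
)


def test_toy_reference_is_deterministic(tmp_path):
    r1 = build_toy_reference(0)
    r2 = build_toy_reference(0)
    assert r1.genome == r2.genome
    p1 = r1.write(tmp_path / "a")
    p2 = r2.write(tmp_path / "b")
    for key in p1:
        assert p1[key].read_bytes() == p2[key].read_bytes()


def test_mature_arms_inside_their_primaries(toy_ref):
    prim = {p.accession: p.interval for p in toy_ref.mirna_primary}
    for m in toy_ref.mirna_mature:
        p = prim[m.derives_from]
        assert m.interval.start >= p.start and m.interval.end <= p.end
        assert m.interval.strand == p.strand


def test_pool_layout_matches_annotation_layers(toy_ref, bundle):
    """A probe read in the middle of every pooled source lands in the layer
    the class promises (exon/intron/trna/repeat/unannotated)."""
    from stakit.assign import Alignment
    from stakit.intervals import GenomicInterval
    from stakit.simulate import CLASS_CATEGORY

    for cls, sources in toy_ref.pools.items():
        for src in sources:
            ex = src.exons[-1]
            mid = (ex.start + ex.end) // 2
            probe = Alignment(
                "probe", GenomicInterval(ex.chrom, mid, mid + 1, ex.strand)
            )
            assert categorize_read(probe, bundle) == CLASS_CATEGORY[cls], (
                cls, src.source_id,
            )


def test_library_outputs_byte_identical_under_same_seed(tmp_path, toy_ref):
    cfg = SimConfig(seed=21, n_reads=800)
    for run in ("x", "y"):
        lib = simulate_library(toy_ref, cfg)
        d = tmp_path / run
        d.mkdir()
        lib.write_fastq(d / "reads.fastq.gz")
        lib.write_truth_bed(d / "truth.bed")
        lib.write_truth_tsv(d / "truth.tsv")
    for name in ("reads.fastq.gz", "truth.bed", "truth.tsv"):
        assert (tmp_path / "x" / name).read_bytes() == (tmp_path / "y" / name).read_bytes()
    other = simulate_library(toy_ref, SimConfig(seed=22, n_reads=800))
    lib = simulate_library(toy_ref, cfg)
    assert [r.sequence for r in other.reads] != [r.sequence for r in lib.reads]


def test_class_mix_recovered_within_binomial_error(toy_ref):
    """With no size-selection losses, per-class read fractions are binomial
    around the configured mix."""
    mix = {"miRNA": 0.3, "snoRNA": 0.3, "tRNA": 0.4}
    n = 20_000
    lib = simulate_library(
        toy_ref, SimConfig(seed=23, n_reads=n, class_mix=mix, error_rate=0.0)
    )
    assert len(lib.reads) == n
    got = lib.class_fractions()
    for cls, p in mix.items():
        sd = np.sqrt(p * (1 - p) / n)
        assert abs(got[cls] - p) < 3 * sd, cls


def test_pap_control_drops_everything_but_preadenylated_mrna(toy_ref):
    mix = {"mRNA": 0.4, "miRNA": 0.3, "tRNA": 0.3}
    with_pap = simulate_library(toy_ref, SimConfig(seed=24, n_reads=3000, class_mix=mix))
    without_pap = simulate_library(
        toy_ref, SimConfig(seed=24, n_reads=3000, class_mix=mix, pap_enabled=False)
    )
    assert {r.rna_class for r in without_pap.reads} == {"mRNA"}
    # the mRNA reads themselves are untouched by the control
    mrna_on = [(r.read_id, r.sequence) for r in with_pap.reads if r.rna_class == "mRNA"]
    mrna_off = [(r.read_id, r.sequence) for r in without_pap.reads]
    assert mrna_on == mrna_off


def test_rt_control_yields_no_reads(toy_ref):
    lib = simulate_library(
        toy_ref, SimConfig(seed=25, n_reads=1000, rt_enabled=False)
    )
    assert lib.reads == []


def test_anchored_insert_lengths_follow_truncated_geometric(toy_ref):
    """Insert lengths of 3'-anchored long-RNA reads match the geometric
    model (capped at the spliced transcript length) in the mean."""
    p = 0.01
    n = 10_000
    lib = simulate_library(
        toy_ref,
        SimConfig(seed=26, n_reads=n, class_mix={"mRNA": 1.0},
                  rt_dropoff_p=p, error_rate=0.0, size_window=(1, 10_000)),
    )
    assert len(lib.reads) == n
    lengths = np.array([r.insert_length for r in lib.reads])
    cap = 420  # exonic length of every toy protein-coding transcript
    expected = (1 - (1 - p) ** cap) / p  # E[min(Geom(p), cap)]
    se = lengths.std(ddof=1) / np.sqrt(n)
    assert abs(lengths.mean() - expected) < 3 * se


def test_three_prime_bias_strengthens_with_dropoff(toy_ref):
    masses = []
    pcg = [t for t in toy_ref.transcripts if t.biotype == "protein_coding"]
    for p in (0.005, 0.02):
        lib = simulate_library(
            toy_ref,
            SimConfig(seed=27, n_reads=6000, class_mix={"mRNA": 1.0},
                      rt_dropoff_p=p, error_rate=0.0),
        )
        profile = gene_body_coverage(lib.truth_alignments(), pcg)
        masses.append(profile.three_prime_mass)
    assert masses[0] > 0.5
    assert masses[1] > masses[0]


def test_truth_alignments_mirror_reads(tmp_path, default_library):
    alns = emit_truth_alignments(default_library, tmp_path / "truth.bed")
    assert len(alns) == len(default_library.reads)
    lines = (tmp_path / "truth.bed").read_text().splitlines()
    assert len(lines) == len(alns)
    for aln_obj, read in zip(alns, default_library.reads):
        assert aln_obj.interval == read.interval
        assert aln_obj.interval.strand == read.interval.strand


def test_truth_interval_contains_visible_insert(default_library, toy_ref):
    """Truth footprints stay within the source molecule's exonic span."""
    sources = {
        src.source_id: src for pool in toy_ref.pools.values() for src in pool
    }
    for r in default_library.reads:
        src = sources[r.source_id]
        lo = min(e.start for e in src.exons)
        hi = max(e.end for e in src.exons)
        assert lo <= r.interval.start < r.interval.end <= hi


def test_substitution_errors_perturb_reads(toy_ref):
    """With a high error rate most arm reads differ from the clean
    insert+tail template; with error rate 0 every read matches it."""
    genome = toy_ref.genome["chrS"]
    arms = {src.source_id: src.exons[0] for src in toy_ref.pools["miRNA"]}

    def template(read):
        arm = arms[read.source_id]
        seq = genome[arm.start:arm.end]
        if arm.strand == "-":
            from stakit.simulate import revcomp

            seq = revcomp(seq)
        return (seq + "A" * read.tail_length)[:50]

    clean = simulate_library(
        toy_ref, SimConfig(seed=28, n_reads=400, class_mix={"miRNA": 1.0},
                           error_rate=0.0)
    )
    assert all(r.sequence == template(r) for r in clean.reads)
    noisy = simulate_library(
        toy_ref, SimConfig(seed=28, n_reads=400, class_mix={"miRNA": 1.0},
                           error_rate=0.1)
    )
    n_diff = sum(r.sequence != template(r) for r in noisy.reads)
    assert n_diff > len(noisy.reads) * 0.9


def test_impossible_size_window_raises(toy_ref):
    with pytest.raises(SimulationError, match="size_window"):
        simulate_library(
            toy_ref,
            SimConfig(seed=29, n_reads=100, class_mix={"miRNA": 1.0},
                      size_window=(25, 30)),  # arms are 22 nt
        )


def test_bad_configs_rejected(toy_ref):
    with pytest.raises(SimulationError, match="class_mix"):
        SimConfig(class_mix={"miRNA": 0.5}).validate()
    with pytest.raises(SimulationError, match="rt_dropoff"):
        SimConfig(rt_dropoff_p=0.0).validate()
    with pytest.raises(SimulationError, match="unknown RNA"):
        SimConfig(class_mix={"piRNA": 1.0}).validate()
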