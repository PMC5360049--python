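"""Chemistry-aware synthetic libraries with per-read ground truth.

The generative model follows the single-tube total-RNA protocol: after
lysis, a poly(A) polymerase (PAP) tails every RNA 3' end; an anchored
oligo-dT primer then primes reverse transcription at the tail/insert
junction, so each read is a 5' insert followed by an encoded A tail.
Consequences modeled here:

* **short RNAs** (miRNA arms, snoRNA, tRNA) are captured whole;
* **long RNAs** (mRNA, rRNA-like) fragment during RT: the insert is
  anchored at the poly(A)-proximal 3' end and extends 5'-ward with a
  per-base termination probability ``rt_dropoff_p``, giving geometric
  insert lengths and the characteristic 3' coverage bias;
* **intronic and repeat-derived fragments** are tailed wherever they were
  cleaved, so their 3' anchor is uniform within the source feature;
* **controls**: without PAP only pre-polyadenylated (mRNA-class) molecules
  can prime; without reverse transcriptase nothing is amplified at all;
* **size selection** keeps inserts inside a length window; a lognormal
  per-molecule amplification weight can duplicate molecules (off by
  default so read counts equal molecule counts).

Everything is deterministic under a fixed seed: identical seed + config
give byte-identical FASTQ/BED/TSV outputs.

The bundled toy reference is a ~100 kb genome carrying every feature class
plus deliberate overlap constructions (a repeat under an exon, an antisense
gene pair) used to exercise assignment priority and strandedness.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Union

import numpy as np

from .annotation import AnnotationBundle, MirnaFeature, TranscriptModel
from .assign import Alignment
from .intervals import GenomicInterval

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: class -> truth category under the bundled toy annotation
CLASS_CATEGORY = {
    "mRNA": "exon",
    "snoRNA": "exon",
    "miRNA": "exon",
    "intronic": "intron",
    "tRNA": "trna",
    "repeat_derived": "repeat",
    "rRNA": "unannotated",
}

#: default per-class molecule fractions.  Chosen so that the resulting
#: category and RNA-type proportions resemble a real tail-anchored total-RNA
#: library from low-input cells: a minority of exon reads dominated by
#: protein-coding fragments, substantial intronic/repeat/tRNA signal, and a
#: large unannotated share from rRNA missing in gene-model annotation.
DEFAULT_CLASS_MIX = {
    "mRNA": 0.07,
    "snoRNA": 0.03,
    "miRNA": 0.02,
    "intronic": 0.21,
    "tRNA": 0.10,
    "repeat_derived": 0.20,
    "rRNA": 0.37,
}

_SHORT = {"miRNA", "snoRNA", "tRNA"}
_ANCHORED = {"mRNA", "rRNA"}
_FRAGMENT = {"intronic", "repeat_derived"}


class SimulationError(ValueError):
    """Contradictory simulator configuration."""


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters; defaults are the reference conditions."""

    seed: int = 0
    n_reads: int = 50_000
    read_length: int = 50
    class_mix: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_MIX)
    )
    tail_length_dist: tuple = ("constant", {"length": 20})
    rt_dropoff_p: float = 0.01
    amp_bias_sigma: float = 0.0
    error_rate: float = 0.001
    size_window: tuple[int, int] = (18, 300)
    pap_enabled: bool = True
    rt_enabled: bool = True

    def validate(self) -> None:
        total = sum(self.class_mix.values())
        if abs(total - 1.0) > 1e-6:
            raise SimulationError(f"class_mix sums to {total}, expected 1")
        if any(v < 0 for v in self.class_mix.values()):
            raise SimulationError("class_mix fractions must be >= 0")
        if not 0 < self.rt_dropoff_p < 1:
            raise SimulationError("rt_dropoff_p must be in (0,1)")
        if not 0 <= self.error_rate <= 1:
            raise SimulationError("error_rate must be in [0,1]")
        lo, hi = self.size_window
        if not (1 <= lo <= hi):
            raise SimulationError(f"bad size_window {self.size_window}")
        if self.amp_bias_sigma < 0:
            raise SimulationError("amp_bias_sigma must be >= 0")
        unknown = set(self.class_mix) - set(CLASS_CATEGORY)
        if unknown:
            raise SimulationError(f"unknown RNA classes: {sorted(unknown)}")

    def as_dict(self) -> dict:
        return {
            "seed": self.seed,
            "n_reads": self.n_reads,
            "read_length": self.read_length,
            "class_mix": dict(self.class_mix),
            "tail_length_dist": [self.tail_length_dist[0], dict(self.tail_length_dist[1])],
            "rt_dropoff_p": self.rt_dropoff_p,
            "amp_bias_sigma": self.amp_bias_sigma,
            "error_rate": self.error_rate,
            "size_window": list(self.size_window),
            "pap_enabled": self.pap_enabled,
            "rt_enabled": self.rt_enabled,
        }


@dataclass(frozen=True)
class SimSource:
    """One sampling source: a molecule (short), a spliced transcript
    (anchored) or a feature fragments are cleaved from (fragment)."""

    source_id: str
    rna_class: str
    exons: tuple[GenomicInterval, ...]  # genomic order

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom


@dataclass(frozen=True)
class SimRead:
    """One emitted read with its complete ground truth."""

    read_id: str
    molecule_id: str
    sequence: str
    qualities: str
    rna_class: str
    source_id: str
    interval: GenomicInterval  # genomic footprint of the read-covered insert
    category: str
    tail_length: int
    insert_length: int  # full insert (pre read-length truncation)


@dataclass
class SimLibrary:
    """Simulated library: reads plus the config that produced them."""

    config: SimConfig
    reads: list[SimRead]

    def truth_alignments(self) -> list[Alignment]:
        return [Alignment(r.read_id, r.interval) for r in self.reads]

    def class_fractions(self) -> dict[str, float]:
        n = len(self.reads)
        out: dict[str, float] = {}
        for r in self.reads:
            out[r.rna_class] = out.get(r.rna_class, 0) + 1
        return {k: v / n for k, v in sorted(out.items())} if n else {}

    def write_fastq(self, path: Union[str, Path]) -> None:
        with _open_w(path) as fh:
            for r in self.reads:
                fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{r.qualities}\n")

    def write_truth_bed(self, path: Union[str, Path]) -> None:
        with _open_w(path) as fh:
            for r in self.reads:
                iv = r.interval
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{r.read_id}\t0\t{iv.strand}\n")

    def write_truth_tsv(self, path: Union[str, Path]) -> None:
        cols = (
            "read_id\tmolecule_id\trna_class\tsource_id\tchrom\tstart\tend\t"
            "strand\tcategory\ttail_length\tinsert_length\n"
        )
        with _open_w(path) as fh:
            fh.write(cols)
            for r in self.reads:
                iv = r.interval
                fh.write(
                    f"{r.read_id}\t{r.molecule_id}\t{r.rna_class}\t{r.source_id}\t"
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.strand}\t{r.category}\t"
                    f"{r.tail_length}\t{r.insert_length}\n"
                )

    def write_config(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(self.config.as_dict(), indent=2) + "\n")


def _open_w(path: Union[str, Path]):
    path = Path(path)
    if path.suffix == ".gz":
        return _TextGz(path)
    return open(path, "w")


class _TextGz:
    """Deterministic text-mode gzip writer (fixed mtime, no filename)."""

    def __init__(self, path: Path) -> None:
        self._raw = open(path, "wb")
        self._gz = gzip.GzipFile(fileobj=self._raw, mode="wb", filename="", mtime=0)

    def write(self, s: str) -> int:
        return self._gz.write(s.encode())

    def __enter__(self) -> "_TextGz":
        return self

    def __exit__(self, *exc) -> None:
        self._gz.close()
        self._raw.close()


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


# --------------------------------------------------------------------------
# toy reference
# --------------------------------------------------------------------------


@dataclass
class ToyReference:
    """Deterministic small genome with layered annotation and class pools."""

    genome: dict[str, str]
    transcripts: list[TranscriptModel]
    trna: list[GenomicInterval]
    trna_ids: list[str]
    repeats: list[GenomicInterval]
    repeat_ids: list[str]
    mirna_primary: list[MirnaFeature]
    mirna_mature: list[MirnaFeature]
    pools: dict[str, list[SimSource]]

    def bundle(self) -> AnnotationBundle:
        return AnnotationBundle.build(
            self.transcripts,
            self.trna,
            self.repeats,
            self.mirna_primary,
            self.mirna_mature,
        )

    def write(self, outdir: Union[str, Path]) -> dict[str, Path]:
        from Bio.Seq import Seq
        from Bio.SeqIO import write as seqio_write
        from Bio.SeqRecord import SeqRecord

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": outdir / "genome.fa",
            "gtf": outdir / "genes.gtf",
            "trna": outdir / "trna.bed",
            "repeats": outdir / "repeats.bed",
            "mirna": outdir / "mirna.gff3",
        }
        records = [
            SeqRecord(Seq(seq), id=chrom, description="")
            for chrom, seq in sorted(self.genome.items())
        ]
        seqio_write(records, str(paths["genome"]), "fasta")

        with open(paths["gtf"], "w") as fh:
            for t in sorted(self.transcripts, key=lambda t: t.span):
                attrs = (
                    f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}"; '
                    f'gene_type "{t.biotype}";'
                )
                fh.write(
                    f"{t.chrom}\ttoy\ttranscript\t{t.span.start + 1}\t{t.span.end}\t.\t"
                    f"{t.strand}\t.\t{attrs}\n"
                )
                for ex in t.exons:
                    fh.write(
                        f"{t.chrom}\ttoy\texon\t{ex.start + 1}\t{ex.end}\t.\t"
                        f"{t.strand}\t.\t{attrs}\n"
                    )
        with open(paths["trna"], "w") as fh:
            for iv, name in zip(self.trna, self.trna_ids):
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")
        with open(paths["repeats"], "w") as fh:
            for iv, name in zip(self.repeats, self.repeat_ids):
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")
        with open(paths["mirna"], "w") as fh:
            fh.write("##gff-version 3\n")
            for f in self.mirna_primary:
                iv = f.interval
                fh.write(
                    f"{iv.chrom}\t.\tmiRNA_primary_transcript\t{iv.start + 1}\t{iv.end}"
                    f"\t.\t{iv.strand}\t.\tID={f.accession};Name={f.name}\n"
                )
            for f in self.mirna_mature:
                iv = f.interval
                fh.write(
                    f"{iv.chrom}\t.\tmiRNA\t{iv.start + 1}\t{iv.end}\t.\t{iv.strand}"
                    f"\t.\tID={f.accession};Name={f.name};Derives_from={f.derives_from}\n"
                )
        return paths


def build_toy_reference(seed: int = 0, genome_size: int = 100_000) -> ToyReference:
    """Deterministic ~100 kb toy genome exercising every pipeline layer.

    Contents: 10 three-exon protein-coding genes (alternating strands),
    4 miRNA hairpins with 5p/3p mature arms, 3 snoRNA genes, 3 tRNA loci
    (BED layer only), 6 intergenic repeats, one unannotated rRNA-like locus,
    plus two deliberate constructions: a repeat inside a protein-coding exon
    (priority: exon must win) and an antisense gene overlapping another
    gene's exon (strandedness: sense assignment must win).

    The 3'-terminal base of every discrete molecule (transcript ends, mature
    arms, snoRNA/tRNA ends) is forced to a non-A so that an appended poly(A)
    tail is exactly recoverable by the clipper; fragment classes keep random
    ends, as in real cleaved RNA.
    """
    rng = np.random.default_rng(seed)
    chrom = "chrS"
    bases = np.array(list("ACGT"))
    seq = list(rng.choice(bases, size=genome_size))

    transcripts: list[TranscriptModel] = []
    trna: list[GenomicInterval] = []
    trna_ids: list[str] = []
    repeats: list[GenomicInterval] = []
    repeat_ids: list[str] = []
    mirna_primary: list[MirnaFeature] = []
    mirna_mature: list[MirnaFeature] = []
    pools: dict[str, list[SimSource]] = {k: [] for k in CLASS_CATEGORY}

    def force_three_prime_non_a(iv: GenomicInterval) -> None:
        # molecule 3' terminus: last genomic base on '+', first on '-'
        if iv.strand == "+":
            seq[iv.end - 1] = "C"
        else:
            seq[iv.start] = "G"  # revcomp -> C

    cursor = 1000
    gap = 2000
    exon_len, intron_len = 140, 400
    pcg_spans: list[GenomicInterval] = []
    for i in range(1, 11):
        strand = "+" if i % 2 else "-"
        e1 = GenomicInterval(chrom, cursor, cursor + exon_len, strand)
        i1 = GenomicInterval(chrom, e1.end, e1.end + intron_len, strand)
        e2 = GenomicInterval(chrom, i1.end, i1.end + exon_len, strand)
        i2 = GenomicInterval(chrom, e2.end, e2.end + intron_len, strand)
        e3 = GenomicInterval(chrom, i2.end, i2.end + exon_len, strand)
        span = GenomicInterval(chrom, e1.start, e3.end, strand)
        gid, tid = f"PCG{i:02d}", f"PCG{i:02d}T1"
        t = TranscriptModel(gid, tid, "protein_coding", span, (e1, e2, e3))
        transcripts.append(t)
        pcg_spans.append(span)
        force_three_prime_non_a(span)
        pools["mRNA"].append(SimSource(tid, "mRNA", (e1, e2, e3)))
        for k, intron in enumerate((i1, i2), 1):
            pools["intronic"].append(
                SimSource(f"{tid}_intron{k}", "intronic", (intron,))
            )
        cursor = span.end + gap

    # antisense partner over PCG01 exon2 (decorative; strandedness test case)
    pcg01 = transcripts[0]
    ex2 = pcg01.exons[1]
    as_iv = GenomicInterval(chrom, ex2.start - 30, ex2.end + 30, "-")
    transcripts.append(
        TranscriptModel("AS01", "AS01T1", "antisense", as_iv, (as_iv,))
    )

    # repeat under PCG03 exon1 (decorative; priority test case)
    ex1_pcg03 = transcripts[2].exons[0]
    repeats.append(
        GenomicInterval(chrom, ex1_pcg03.start + 20, ex1_pcg03.start + 120,
                        transcripts[2].strand)
    )
    repeat_ids.append("REP_under_exon")

    arm_rel = ((10, 32), (48, 70))
    for j in range(1, 5):
        strand = "+" if j % 2 else "-"
        prim = GenomicInterval(chrom, cursor, cursor + 80, strand)
        acc = f"MI{j:07d}"
        mirna_primary.append(MirnaFeature(prim, accession=acc, name=f"toy-mir-{j}"))
        gid = f"MIRG{j}"
        transcripts.append(
            TranscriptModel(gid, f"{gid}T1", "miRNA", prim, (prim,))
        )
        for a, (lo, hi) in enumerate(arm_rel):
            arm = GenomicInterval(chrom, cursor + lo, cursor + hi, strand)
            # genomically left arm is 5p on '+', 3p on '-'
            side = ("5p", "3p")[a] if strand == "+" else ("3p", "5p")[a]
            feat = MirnaFeature(
                arm,
                accession=f"MIMAT{2 * j - 1 + a:07d}",
                name=f"toy-miR-{j}-{side}",
                derives_from=acc,
            )
            mirna_mature.append(feat)
            force_three_prime_non_a(arm)
            pools["miRNA"].append(SimSource(feat.accession, "miRNA", (arm,)))
        cursor = prim.end + gap

    for k in range(1, 4):
        strand = "+" if k % 2 else "-"
        iv = GenomicInterval(chrom, cursor, cursor + 70, strand)
        gid = f"SNO{k}"
        transcripts.append(TranscriptModel(gid, f"{gid}T1", "snoRNA", iv, (iv,)))
        force_three_prime_non_a(iv)
        pools["snoRNA"].append(SimSource(gid, "snoRNA", (iv,)))
        cursor = iv.end + gap

    for m in range(1, 4):
        strand = "+" if m % 2 else "-"
        iv = GenomicInterval(chrom, cursor, cursor + 72, strand)
        trna.append(iv)
        trna_ids.append(f"TRN{m}")
        force_three_prime_non_a(iv)
        pools["tRNA"].append(SimSource(f"TRN{m}", "tRNA", (iv,)))
        cursor = iv.end + gap

    rrna = GenomicInterval(chrom, cursor, cursor + 1500, "+")
    force_three_prime_non_a(rrna)
    pools["rRNA"].append(SimSource("RRNA1", "rRNA", (rrna,)))
    cursor = rrna.end + gap

    for r in range(1, 7):
        strand = "+" if r % 2 else "-"
        iv = GenomicInterval(chrom, cursor, cursor + 300, strand)
        repeats.append(iv)
        repeat_ids.append(f"REP{r}")
        pools["repeat_derived"].append(SimSource(f"REP{r}", "repeat_derived", (iv,)))
        cursor = iv.end + gap

    if cursor > genome_size:
        raise ValueError("toy genome layout exceeds genome_size")

    return ToyReference(
        genome={chrom: "".join(seq)},
        transcripts=transcripts,
        trna=trna,
        trna_ids=trna_ids,
        repeats=repeats,
        repeat_ids=repeat_ids,
        mirna_primary=mirna_primary,
        mirna_mature=mirna_mature,
        pools=pools,
    )


# --------------------------------------------------------------------------
# library simulation
# --------------------------------------------------------------------------


def _spliced(reference: ToyReference, src: SimSource, cache: dict):
    """5'→3' spliced genomic positions and sequence for a source."""
    hit = cache.get(src.source_id)
    if hit is not None:
        return hit
    exons = sorted(src.exons, key=lambda e: e.start)
    positions = np.concatenate([np.arange(e.start, e.end) for e in exons])
    genome_seq = reference.genome[src.chrom]
    s = "".join(genome_seq[e.start:e.end] for e in exons)
    if src.strand == "-":
        positions = positions[::-1]
        s = revcomp(s)
    cache[src.source_id] = (positions, s)
    return positions, s


def _draw_tail(rng: np.random.Generator, dist: tuple) -> int:
    name, params = dist
    if name == "constant":
        return int(params["length"])
    if name == "uniform":
        return int(rng.integers(params["low"], params["high"] + 1))
    if name == "geometric":
        return int(params.get("min", 9) + rng.geometric(params["p"]) - 1)
    raise SimulationError(f"unknown tail_length_dist {name!r}")


def simulate_library(reference: ToyReference, config: SimConfig) -> SimLibrary:
    """Generate one library from a reference under a configuration.

    Per molecule: draw class, then a source uniformly within the class pool;
    derive the insert according to the class kind (whole molecule, 3'-end
    anchored geometric, or cleaved fragment); draw a tail length; apply the
    size window; duplicate by the amplification weight; append the tail,
    truncate to the read length and apply substitution errors per copy.

    Random draws are made for every molecule regardless of the PAP/RT
    control gates and the size window, so toggling a control changes which
    reads are emitted but never the content of the reads that remain.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    class_names = sorted(config.class_mix)
    probs = np.array([config.class_mix[c] for c in class_names], dtype=float)
    probs = probs / probs.sum()
    for cls, p in zip(class_names, probs):
        if p > 0 and not reference.pools.get(cls):
            raise SimulationError(f"class {cls!r} has no sources in the reference")
    class_idx = rng.choice(len(class_names), size=config.n_reads, p=probs)
    lo, hi = config.size_window
    cache: dict = {}
    reads: list[SimRead] = []
    n_permitted = 0
    n_size_dropped = 0
    for i in range(config.n_reads):
        cls = class_names[class_idx[i]]
        pool = reference.pools[cls]
        src = pool[int(rng.integers(len(pool)))]
        positions, spliced_seq = _spliced(reference, src, cache)
        n = len(spliced_seq)
        if cls in _SHORT:
            a, b = 0, n
        elif cls in _ANCHORED:
            length = int(min(rng.geometric(config.rt_dropoff_p), n))
            a, b = n - length, n
        else:  # fragment: random cleavage point is the 3' anchor
            end_off = int(rng.integers(1, n + 1))
            length = int(min(rng.geometric(config.rt_dropoff_p), end_off))
            a, b = end_off - length, end_off
        insert_len = b - a
        tail_len = _draw_tail(rng, config.tail_length_dist)
        if config.amp_bias_sigma > 0:
            weight = rng.lognormal(0.0, config.amp_bias_sigma)
            copies = max(1, int(rng.poisson(weight)))
        else:
            copies = 1
        insert_seq = spliced_seq[a:b]
        template = insert_seq + "A" * tail_len
        emit_seq = template[: config.read_length]
        visible = min(insert_len, config.read_length)
        cov = positions[a : a + visible]
        footprint = GenomicInterval(
            src.chrom, int(cov.min()), int(cov.max()) + 1, src.strand
        )
        permitted = config.rt_enabled and (config.pap_enabled or cls == "mRNA")
        in_window = lo <= insert_len <= hi
        if permitted:
            n_permitted += copies
            if not in_window:
                n_size_dropped += copies
        for c in range(copies):
            if config.error_rate > 0:
                draws = rng.random(len(emit_seq))
                err_pos = np.flatnonzero(draws < config.error_rate)
                alt_draws = rng.integers(0, 3, size=len(err_pos))
            else:
                err_pos, alt_draws = np.zeros(0, dtype=int), np.zeros(0, dtype=int)
            if not (permitted and in_window):
                continue
            read_seq = emit_seq
            if len(err_pos):
                chars = list(read_seq)
                for pos, alt in zip(err_pos, alt_draws):
                    options = [x for x in "ACGT" if x != chars[pos]]
                    chars[pos] = options[alt]
                read_seq = "".join(chars)
            reads.append(
                SimRead(
                    read_id=f"sim{i:06d}.{c}",
                    molecule_id=f"mol{i:06d}",
                    sequence=read_seq,
                    qualities="I" * len(read_seq),
                    rna_class=cls,
                    source_id=src.source_id,
                    interval=footprint,
                    category=CLASS_CATEGORY[cls],
                    tail_length=tail_len,
                    insert_length=insert_len,
                )
            )
    if n_permitted > 0 and not reads and n_size_dropped == n_permitted:
        raise SimulationError(
            f"size_window {config.size_window} excluded every molecule"
        )
    return SimLibrary(config=config, reads=reads)


def emit_truth_alignments(
    library: SimLibrary, bed_path: Optional[Union[str, Path]] = None
) -> list[Alignment]:
    """Perfect alignments of the simulated reads (one BED6 record each).

    These stand in for an external aligner when testing the assignment,
    miRNA and QC stages; byte-deterministic under a fixed seed.
    """
    if bed_path is not None:
        library.write_truth_bed(bed_path)
    return library.truth_alignments()
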