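"""Strand-aware, hierarchical assignment of aligned reads to features.

Each primary alignment is assigned to exactly one category by checking the
annotation layers in fixed priority order — exon, intron, tRNA, repeat —
and taking the first layer with a same-strand overlap of at least
``min_overlap`` bases.  Reads matching no layer on their own strand are
*unannotated*; in particular, a read lying antisense to an exon or intron
is unannotated, because the chemistry is forward-stranded (the clipped
insert reads sense to the transcript).

Two counting conventions coexist deliberately:

* category counting assigns each read once (category totals always sum to
  the number of aligned reads);
* gene counting follows multicov semantics — a read overlapping the merged
  exons of two genes increments both.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Union

import pandas as pd
import pysam

from .annotation import AnnotationBundle
from .intervals import ContractError, GenomicInterval, opposite_strand

CATEGORIES = ("exon", "intron", "trna", "repeat", "unannotated")
LAYER_ORDER = ("exon", "intron", "trna", "repeat")
STRAND_MODES = ("forward", "reverse", "both")


@dataclass(frozen=True)
class Alignment:
    """One aligned read: its id and reference footprint.

    The footprint is the reference span of the alignment; splice gaps are
    included in the span for overlap purposes, matching interval-overlap
    tools.
    """

    read_id: str
    interval: GenomicInterval
    is_primary: bool = True
    mapq: int = 255


@dataclass
class CategoryCounts:
    """Per-library read totals by feature category."""

    exon: int = 0
    intron: int = 0
    trna: int = 0
    repeat: int = 0
    unannotated: int = 0
    library_id: Optional[str] = None

    @property
    def aligned_total(self) -> int:
        return self.exon + self.intron + self.trna + self.repeat + self.unannotated

    def as_dict(self) -> dict[str, int]:
        return {c: getattr(self, c) for c in CATEGORIES}

    def fractions(self) -> dict[str, float]:
        total = self.aligned_total
        if total == 0:
            return {c: 0.0 for c in CATEGORIES}
        return {c: getattr(self, c) / total for c in CATEGORIES}


@dataclass
class GeneCounts:
    """Per-gene read counts (multicov semantics) for one library."""

    counts: dict[str, int]
    library_id: Optional[str] = None

    def as_series(self) -> pd.Series:
        return pd.Series(self.counts, name=self.library_id or "count").sort_index()


@dataclass
class BiotypeSummary:
    """Exon-category reads tallied by the biotype of the overlapped gene."""

    counts: dict[str, int] = field(default_factory=dict)
    exon_total: int = 0
    library_id: Optional[str] = None

    def fractions(self) -> dict[str, float]:
        if self.exon_total == 0:
            return {}
        return {bt: n / self.exon_total for bt, n in sorted(self.counts.items())}


def _layer_indexes(bundle: AnnotationBundle):
    return (
        ("exon", bundle.exon_index),
        ("intron", bundle.intron_index),
        ("trna", bundle.trna_index),
        ("repeat", bundle.repeat_index),
    )


def categorize_read(
    aln: Alignment, bundle: AnnotationBundle, min_overlap: int = 1
) -> str:
    """First layer (exon > intron > tRNA > repeat) with a same-strand overlap
    of >= min_overlap bases, else "unannotated"."""
    if not aln.is_primary:
        raise ContractError("categorize_read requires primary alignments")
    for name, index in _layer_indexes(bundle):
        if index.any_overlap(aln.interval, min_overlap):
            return name
    return "unannotated"


def count_categories(
    alignments: Iterable[Alignment],
    bundle: AnnotationBundle,
    min_overlap: int = 1,
    library_id: Optional[str] = None,
) -> CategoryCounts:
    """Count each primary alignment exactly once by category."""
    counts = CategoryCounts(library_id=library_id)
    for aln in alignments:
        cat = categorize_read(aln, bundle, min_overlap)
        setattr(counts, cat, getattr(counts, cat) + 1)
    return counts


def _query_interval(iv: GenomicInterval, strand_mode: str) -> GenomicInterval:
    if strand_mode == "forward":
        return iv
    if strand_mode == "reverse":
        return GenomicInterval(iv.chrom, iv.start, iv.end, opposite_strand(iv.strand))
    if strand_mode == "both":
        return GenomicInterval(iv.chrom, iv.start, iv.end, ".")
    raise ValueError(f"strand_mode must be one of {STRAND_MODES}, got {strand_mode!r}")


def count_genes(
    alignments: Iterable[Alignment],
    bundle: AnnotationBundle,
    strand_mode: str = "forward",
    min_overlap: int = 1,
    library_id: Optional[str] = None,
) -> GeneCounts:
    """Per-gene alignment counts over merged exons (multicov semantics).

    Every gene in the bundle is reported, zeros included.  A read whose
    footprint overlaps the exons of several genes on the required strand
    increments each of them.
    """
    counts = {gid: 0 for gid in bundle.gene_exons}
    for aln in alignments:
        if not aln.is_primary:
            raise ContractError("count_genes requires primary alignments")
        query = _query_interval(aln.interval, strand_mode)
        per_gene: dict[str, int] = {}
        for _feat, gid, ov in bundle.exon_index.hits(query):
            per_gene[gid] = per_gene.get(gid, 0) + ov
        for gid, ov in per_gene.items():
            if ov >= min_overlap:
                counts[gid] += 1
    return GeneCounts(counts=counts, library_id=library_id)


def summarize_biotypes(
    alignments: Iterable[Alignment],
    bundle: AnnotationBundle,
    min_overlap: int = 1,
    library_id: Optional[str] = None,
) -> BiotypeSummary:
    """RNA-type summary of exon-category reads.

    Each exon read contributes once, to the biotype of the gene it overlaps
    most (ties broken by lexicographic gene id — deterministic).
    """
    summary = BiotypeSummary(library_id=library_id)
    for aln in alignments:
        if categorize_read(aln, bundle, min_overlap) != "exon":
            continue
        per_gene: dict[str, int] = {}
        for _feat, gid, ov in bundle.exon_index.hits(aln.interval):
            per_gene[gid] = per_gene.get(gid, 0) + ov
        winner = min(per_gene.items(), key=lambda kv: (-kv[1], kv[0]))[0]
        biotype = bundle.gene_biotype.get(winner, "unknown")
        summary.counts[biotype] = summary.counts.get(biotype, 0) + 1
        summary.exon_total += 1
    return summary


def filter_summed_counts(matrix: pd.DataFrame, threshold: int) -> pd.DataFrame:
    """Keep features whose count summed across libraries exceeds ``threshold``.

    The inequality is strict: a feature summing to exactly ``threshold`` is
    dropped.  This is the generic "summed counts > N" pre-filter applied
    before downstream expression analysis.
    """
    return matrix.loc[matrix.sum(axis=1) > threshold]


# -- alignment input ---------------------------------------------------------


def read_alignments_bed(path: Union[str, Path]) -> list[Alignment]:
    """Load alignments from BED6 (e.g. the simulator's truth BED)."""
    out: list[Alignment] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}:{lineno}: alignment BED needs 6 columns")
            out.append(
                Alignment(
                    read_id=fields[3],
                    interval=GenomicInterval(
                        fields[0], int(fields[1]), int(fields[2]), fields[5]
                    ),
                    mapq=int(fields[4]) if fields[4].isdigit() else 255,
                )
            )
    return out


def read_alignments_bam(path: Union[str, Path]) -> list[Alignment]:
    """Load primary alignments from SAM/BAM/CRAM.

    Secondary, supplementary and unmapped records are skipped; the read
    strand is the alignment strand.
    """
    out: list[Alignment] = []
    mode = "r" if str(path).endswith(".sam") else "rb"
    with pysam.AlignmentFile(str(path), mode) as bam:
        for rec in bam.fetch(until_eof=True):
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            out.append(
                Alignment(
                    read_id=rec.query_name,
                    interval=GenomicInterval(
                        rec.reference_name,
                        rec.reference_start,
                        rec.reference_end,
                        "-" if rec.is_reverse else "+",
                    ),
                    mapq=rec.mapping_quality,
                )
            )
    return out


def load_alignments(path: Union[str, Path]) -> list[Alignment]:
    """Dispatch on extension: .bed -> BED6, .sam/.bam/.cram -> pysam."""
    s = str(path)
    if s.endswith(".bed") or s.endswith(".bed.gz"):
        return read_alignments_bed(path)
    return read_alignments_bam(path)
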