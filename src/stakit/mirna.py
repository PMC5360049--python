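"""Mature-miRNA quantification by exclusion of precursor/loop reads.

A hairpin precursor is longer than its processed ~22-nt arms, so reads from
unprocessed precursor, loop, or flanking regions would inflate mature
counts.  The procedure used here mirrors the subtract/intersect idiom of
genomic-arithmetic tools:

1. derive the *non-mature* region = precursor minus mature arms (per base,
   per strand — see :func:`stakit.annotation.derive_nonmature`);
2. remove every read with any same-strand overlap with that region
   (a single overlapping base is enough, the intersect default);
3. count the surviving reads against the mature arms, multicov-style
   (a read overlapping two arms increments both).

Counts are keyed by mature accession when present, falling back to the
feature name.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Union

from .annotation import MirnaFeature, derive_nonmature
from .assign import Alignment
from .intervals import GenomicInterval, StrandedIndex


@dataclass
class MatureCounts:
    """Per-arm mature miRNA counts plus removal bookkeeping."""

    counts: dict[str, int] = field(default_factory=dict)
    removed_reads: int = 0
    input_reads: int = 0
    library_id: Optional[str] = None

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def remove_nonmature_reads(
    alignments: Iterable[Alignment],
    nonmature: Iterable[GenomicInterval],
    min_overlap: int = 1,
) -> list[Alignment]:
    """Retain alignments with zero same-strand overlap with any non-mature
    interval (>= min_overlap bases triggers removal)."""
    index = StrandedIndex(nonmature)
    return [
        aln
        for aln in alignments
        if not index.any_overlap(aln.interval, min_overlap)
    ]


def count_mature(
    alignments: Iterable[Alignment],
    mature: Iterable[MirnaFeature],
    min_overlap: int = 1,
    require_containment: bool = False,
) -> dict[str, int]:
    """Count surviving alignments per mature arm (multicov semantics).

    With ``require_containment=True`` a read must lie entirely inside the
    arm instead of merely overlapping it.
    """
    mature = list(mature)
    index = StrandedIndex((f.interval, f.key) for f in mature)
    counts = {f.key: 0 for f in mature}
    for aln in alignments:
        iv = aln.interval
        for feat, key, ov in index.hits(iv):
            if require_containment:
                if iv.start >= feat.start and iv.end <= feat.end:
                    counts[key] += 1
            elif ov >= min_overlap:
                counts[key] += 1
    return counts


def quantify_mature(
    alignments: Iterable[Alignment],
    primary: Iterable[MirnaFeature],
    mature: Iterable[MirnaFeature],
    min_overlap: int = 1,
    require_containment: bool = False,
    library_id: Optional[str] = None,
) -> MatureCounts:
    """Full remove-then-count pipeline over a precursor/mature annotation."""
    alignments = list(alignments)
    mature = list(mature)
    nonmature = derive_nonmature(primary, mature)
    surviving = remove_nonmature_reads(alignments, nonmature, min_overlap)
    counts = count_mature(
        surviving, mature, min_overlap=min_overlap,
        require_containment=require_containment,
    )
    return MatureCounts(
        counts=counts,
        removed_reads=len(alignments) - len(surviving),
        input_reads=len(alignments),
        library_id=library_id,
    )


def write_mature_counts(
    result: MatureCounts,
    mature: Iterable[MirnaFeature],
    path: Union[str, Path],
) -> None:
    """TSV output: mature_id, name, count."""
    by_key = {}
    for f in mature:
        by_key.setdefault(f.key, f)
    with open(path, "w") as fh:
        fh.write("mature_id\tname\tcount\n")
        for key in sorted(result.counts):
            name = by_key[key].name if key in by_key else ""
            fh.write(f"{key}\t{name or ''}\t{result.counts[key]}\n")
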