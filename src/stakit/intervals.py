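"""Stranded genomic intervals and BEDTools-style set algebra.

Every coordinate in this package is 0-based half-open, regardless of the
file format it came from (GTF/GFF3 are converted on ingestion, BED is taken
as-is).  Strand is ``+``, ``-`` or ``.``; a ``.`` interval is strand-agnostic
and matches reads on either strand.

The set operations here (:func:`merge_intervals`, :func:`subtract_intervals`)
are the building blocks for derived annotation layers: introns are
transcript-span minus merged exons, and the non-mature miRNA region is the
hairpin precursor minus its mature arms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Iterable, Optional

from intervaltree import IntervalTree

STRANDS = ("+", "-", ".")


class ContractError(ValueError):
    """An operation was called outside its documented contract."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded 0-based half-open interval on a named sequence."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap_length(self, other: "GenomicInterval") -> int:
        """Overlap in bases with ``other``, ignoring strand (0 if different chrom)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def strands_compatible(self, other: "GenomicInterval") -> bool:
        return strands_compatible(self.strand, other.strand)


def strands_compatible(a: str, b: str) -> bool:
    """Same-strand test where ``.`` is a wildcard on either side."""
    return a == "." or b == "." or a == b


def opposite_strand(strand: str) -> str:
    return {"+": "-", "-": "+", ".": "."}[strand]


def _check_uniform(ivs: list[GenomicInterval], what: str) -> None:
    chroms = {iv.chrom for iv in ivs}
    strands = {iv.strand for iv in ivs}
    if len(chroms) > 1 or len(strands) > 1:
        raise ContractError(
            f"{what} requires intervals on a single chrom and strand, "
            f"got chroms={sorted(chroms)} strands={sorted(strands)}"
        )


def _check_merged(ivs: list[GenomicInterval], what: str) -> None:
    _check_uniform(ivs, what)
    for prev, cur in zip(ivs, ivs[1:]):
        if cur.start < prev.end:
            raise ContractError(f"{what} requires merged (sorted, disjoint) input")


def merge_intervals(ivs: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Minimal sorted set of disjoint intervals covering the same bases.

    Book-ended intervals ([0,10) and [10,20)) are merged, matching half-open
    adjacency.  All inputs must share one chrom and strand.
    """
    ivs = list(ivs)
    if not ivs:
        return []
    _check_uniform(ivs, "merge_intervals")
    ivs.sort(key=lambda iv: (iv.start, iv.end))
    merged: list[GenomicInterval] = []
    cur_start, cur_end = ivs[0].start, ivs[0].end
    for iv in ivs[1:]:
        if iv.start <= cur_end:
            cur_end = max(cur_end, iv.end)
        else:
            merged.append(GenomicInterval(ivs[0].chrom, cur_start, cur_end, ivs[0].strand))
            cur_start, cur_end = iv.start, iv.end
    merged.append(GenomicInterval(ivs[0].chrom, cur_start, cur_end, ivs[0].strand))
    return merged


def subtract_intervals(
    a: Iterable[GenomicInterval], b: Iterable[GenomicInterval]
) -> list[GenomicInterval]:
    """Bases in ``a`` and not in ``b``, as merged intervals.

    Both inputs must already be merged.  The subtraction is strand-aware:
    ``b`` intervals on an incompatible strand (or a different chrom) remove
    nothing.  ``.`` acts as a wildcard on either side.
    """
    a = list(a)
    b = list(b)
    if not a:
        return []
    _check_merged(a, "subtract_intervals (a)")
    if b:
        _check_merged(b, "subtract_intervals (b)")
    chrom, strand = a[0].chrom, a[0].strand
    b = [iv for iv in b if iv.chrom == chrom and strands_compatible(strand, iv.strand)]
    out: list[GenomicInterval] = []
    bi = 0
    for iv in a:
        lo = iv.start
        while bi < len(b) and b[bi].end <= lo:
            bi += 1
        j = bi
        while j < len(b) and b[j].start < iv.end:
            if b[j].start > lo:
                out.append(GenomicInterval(chrom, lo, b[j].start, strand))
            lo = max(lo, b[j].end)
            if lo >= iv.end:
                break
            j += 1
        if lo < iv.end:
            out.append(GenomicInterval(chrom, lo, iv.end, strand))
    return out


class StrandedIndex:
    """Strand-aware interval index answering overlap queries.

    Features on strand ``.`` are indexed on both strands, so strandless
    annotation layers (e.g. repeat tracks without strand) match reads on
    either strand.  Queries with a ``.`` interval likewise search both
    strands.  Payloads must be hashable (feature names / gene ids).
    """

    def __init__(
        self,
        items: Iterable[GenomicInterval | tuple[GenomicInterval, Hashable]] = (),
    ) -> None:
        self._trees: dict[tuple[str, str], IntervalTree] = {}
        self._n = 0
        for item in items:
            if isinstance(item, GenomicInterval):
                self.add(item)
            else:
                self.add(item[0], item[1])

    def __len__(self) -> int:
        return self._n

    def add(self, iv: GenomicInterval, payload: Optional[Hashable] = None) -> None:
        strands = ("+", "-") if iv.strand == "." else (iv.strand,)
        for s in strands:
            self._trees.setdefault((iv.chrom, s), IntervalTree()).addi(
                iv.start, iv.end, (iv, payload)
            )
        self._n += 1

    def hits(self, iv: GenomicInterval) -> list[tuple[GenomicInterval, Hashable, int]]:
        """All overlapping same-strand features as (feature, payload, overlap_bases)."""
        strands = ("+", "-") if iv.strand == "." else (iv.strand,)
        seen: set[tuple[GenomicInterval, Hashable]] = set()
        out: list[tuple[GenomicInterval, Hashable, int]] = []
        for s in strands:
            tree = self._trees.get((iv.chrom, s))
            if tree is None:
                continue
            for hit in tree.overlap(iv.start, iv.end):
                feat, payload = hit.data
                key = (feat, payload)
                if key in seen:
                    continue
                seen.add(key)
                ov = min(iv.end, feat.end) - max(iv.start, feat.start)
                if ov > 0:
                    out.append((feat, payload, ov))
        return out

    def overlap_bases(self, iv: GenomicInterval) -> int:
        """Number of bases of ``iv`` covered by the union of same-strand features."""
        hits = self.hits(iv)
        if not hits:
            return 0
        spans = sorted(
            (max(iv.start, f.start), min(iv.end, f.end)) for f, _, _ in hits
        )
        covered = 0
        cur_s, cur_e = spans[0]
        for s, e in spans[1:]:
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                covered += cur_e - cur_s
                cur_s, cur_e = s, e
        covered += cur_e - cur_s
        return covered

    def any_overlap(self, iv: GenomicInterval, min_overlap: int = 1) -> bool:
        return self.overlap_bases(iv) >= min_overlap

    def intervals(self) -> list[tuple[GenomicInterval, Hashable]]:
        seen: set[tuple[GenomicInterval, Hashable]] = set()
        out = []
        for tree in self._trees.values():
            for hit in tree:
                key = hit.data
                if key not in seen:
                    seen.add(key)
                    out.append(key)
        return sorted(out, key=lambda t: t[0])
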