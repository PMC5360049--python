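"""Layered, strand-aware annotation model.

Four feature layers drive read assignment, in fixed priority order:

1. **exon** — merged exons of every gene (GENCODE-style GTF), with the
   gene's biotype retained for RNA-type summaries;
2. **intron** — derived per transcript as span minus merged exons;
3. **tRNA** — a separate GTF/BED layer (tRNA genes are annotated outside
   the main gene set);
4. **repeat** — a RepeatMasker-style BED track.

A fifth, miRNA-specific pair of sets comes from a miRBase-style GFF3:
``miRNA_primary_transcript`` (hairpin precursors) and ``miRNA`` (mature
arms).  The *non-mature* region — precursor minus mature arms, per base and
per strand — is derived here and used to exclude precursor/loop reads from
mature-miRNA counting.

GTF and GFF3 are 1-based inclusive on disk and converted to 0-based
half-open on ingestion; BED is taken as-is.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

from gffutils.feature import feature_from_line

from .intervals import (
    GenomicInterval,
    StrandedIndex,
    merge_intervals,
    subtract_intervals,
)

logger = logging.getLogger(__name__)

BIOTYPE_KEYS = ("gene_type", "gene_biotype")
TRANSCRIPT_BIOTYPE_KEYS = ("transcript_type", "transcript_biotype")


class AnnotationFormatError(ValueError):
    """Malformed annotation input (GTF/GFF3/BED)."""


@dataclass(frozen=True)
class TranscriptModel:
    """One transcript: id pair, biotype, span and merged exons on one strand."""

    gene_id: str
    transcript_id: str
    biotype: str
    span: GenomicInterval
    exons: tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        for ex in self.exons:
            if ex.chrom != self.span.chrom or ex.strand != self.span.strand:
                raise ValueError(
                    f"transcript {self.transcript_id}: exon on different chrom/strand"
                )
            if ex.start < self.span.start or ex.end > self.span.end:
                raise ValueError(
                    f"transcript {self.transcript_id}: exon outside span"
                )

    @property
    def chrom(self) -> str:
        return self.span.chrom

    @property
    def strand(self) -> str:
        return self.span.strand

    @property
    def exonic_length(self) -> int:
        return sum(ex.length for ex in self.exons)


@dataclass(frozen=True)
class MirnaFeature:
    """A named miRNA record: hairpin precursor or mature arm."""

    interval: GenomicInterval
    accession: Optional[str] = None  # ID attribute (MI/MIMAT-style)
    name: Optional[str] = None  # Name attribute
    derives_from: Optional[str] = None  # precursor accession, mature arms only

    @property
    def key(self) -> str:
        """Counting key: accession when present, else name."""
        if self.accession:
            return self.accession
        if self.name:
            return self.name
        iv = self.interval
        return f"{iv.chrom}:{iv.start}-{iv.end}({iv.strand})"


def _parse_feature_line(line: str, lineno: int, path: str):
    try:
        return feature_from_line(line)
    except Exception as exc:  # gffutils raises assorted exception types
        raise AnnotationFormatError(f"{path}:{lineno}: unparseable line: {exc}") from exc


def _to_interval(feat, lineno: int, path: str) -> GenomicInterval:
    # GTF/GFF3 are 1-based inclusive: [start, end] -> [start-1, end)
    if feat.end < feat.start:
        raise AnnotationFormatError(f"{path}:{lineno}: end < start")
    strand = feat.strand if feat.strand in ("+", "-") else "."
    return GenomicInterval(feat.seqid, feat.start - 1, feat.end, strand)


def _attr(feat, *keys: str) -> Optional[str]:
    for key in keys:
        if key in feat.attributes:
            vals = feat.attributes[key]
            if vals:
                return vals[0]
    return None


def parse_gtf(path: Union[str, Path]) -> list[TranscriptModel]:
    """Parse a GENCODE-dialect GTF into transcript models.

    Exon records are grouped under their transcript; the transcript record,
    when present, supplies the span (otherwise the exon hull is used).  The
    biotype is read from ``gene_type`` or ``gene_biotype`` (transcript-level
    keys as fallback).  Feature types other than transcript/exon are ignored
    with a logged count.
    """
    path = Path(path)
    spans: dict[str, GenomicInterval] = {}
    exons: dict[str, list[GenomicInterval]] = {}
    meta: dict[str, tuple[str, str]] = {}  # tid -> (gene_id, biotype)
    ignored = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            feat = _parse_feature_line(line, lineno, str(path))
            if feat.featuretype not in ("transcript", "exon"):
                ignored += 1
                continue
            iv = _to_interval(feat, lineno, str(path))
            gene_id = _attr(feat, "gene_id")
            tid = _attr(feat, "transcript_id")
            if gene_id is None or tid is None:
                raise AnnotationFormatError(
                    f"{path}:{lineno}: missing gene_id/transcript_id attribute"
                )
            if tid not in meta:
                biotype = (
                    _attr(feat, *BIOTYPE_KEYS)
                    or _attr(feat, *TRANSCRIPT_BIOTYPE_KEYS)
                    or "unknown"
                )
                meta[tid] = (gene_id, biotype)
            if feat.featuretype == "transcript":
                spans[tid] = iv
            else:
                exons.setdefault(tid, []).append(iv)
    if ignored:
        logger.info("parse_gtf(%s): ignored %d non-transcript/exon lines", path, ignored)
    transcripts: list[TranscriptModel] = []
    for tid, (gene_id, biotype) in meta.items():
        tid_exons = merge_intervals(exons.get(tid, []))
        if tid in spans:
            span = spans[tid]
        elif tid_exons:
            span = GenomicInterval(
                tid_exons[0].chrom,
                tid_exons[0].start,
                tid_exons[-1].end,
                tid_exons[0].strand,
            )
        else:
            continue
        if not tid_exons:
            # terse single-record transcripts: whole span is exonic
            tid_exons = [span]
        transcripts.append(
            TranscriptModel(gene_id, tid, biotype, span, tuple(tid_exons))
        )
    if not transcripts:
        logger.warning("parse_gtf(%s): no transcripts found", path)
    return transcripts


def parse_mirna_gff3(
    path: Union[str, Path],
) -> tuple[list[MirnaFeature], list[MirnaFeature]]:
    """Parse a miRBase-dialect GFF3 into (precursor, mature) feature sets.

    Only ``miRNA_primary_transcript`` and ``miRNA`` records are used; other
    feature types are ignored with a logged count.
    """
    path = Path(path)
    primary: list[MirnaFeature] = []
    mature: list[MirnaFeature] = []
    ignored = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            feat = _parse_feature_line(line, lineno, str(path))
            if feat.featuretype not in ("miRNA_primary_transcript", "miRNA"):
                ignored += 1
                continue
            iv = _to_interval(feat, lineno, str(path))
            rec = MirnaFeature(
                interval=iv,
                accession=_attr(feat, "ID"),
                name=_attr(feat, "Name"),
                derives_from=_attr(feat, "Derives_from"),
            )
            if feat.featuretype == "miRNA_primary_transcript":
                primary.append(rec)
            else:
                mature.append(rec)
    if ignored:
        logger.info("parse_mirna_gff3(%s): ignored %d other feature lines", path, ignored)
    return primary, mature


def parse_bed(path: Union[str, Path]) -> list[GenomicInterval]:
    """Parse BED3/BED6 into intervals (already 0-based half-open).

    Records with fewer than six columns, or with strand ``.``, are
    strandless and will match reads on either strand.
    """
    path = Path(path)
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise AnnotationFormatError(f"{path}:{lineno}: fewer than 3 BED columns")
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise AnnotationFormatError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            strand = fields[5] if len(fields) >= 6 else "."
            if strand not in ("+", "-", "."):
                raise AnnotationFormatError(f"{path}:{lineno}: bad strand {strand!r}")
            try:
                out.append(GenomicInterval(chrom, start, end, strand))
            except ValueError as exc:
                raise AnnotationFormatError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_bed(
    ivs: Iterable[GenomicInterval],
    path: Union[str, Path],
    names: Optional[Sequence[str]] = None,
) -> None:
    """Write intervals as BED6 (name '.' unless given, score 0)."""
    ivs = list(ivs)
    if names is None:
        names = ["."] * len(ivs)
    with open(path, "w") as fh:
        for iv, name in zip(ivs, names):
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


def derive_introns(t: TranscriptModel) -> list[GenomicInterval]:
    """Introns of one transcript: span minus merged exons."""
    return subtract_intervals([t.span], list(t.exons))


def _as_intervals(
    feats: Iterable[Union[GenomicInterval, MirnaFeature]]
) -> list[GenomicInterval]:
    return [f.interval if isinstance(f, MirnaFeature) else f for f in feats]


def derive_nonmature(
    primary: Iterable[Union[GenomicInterval, MirnaFeature]],
    mature: Iterable[Union[GenomicInterval, MirnaFeature]],
) -> list[GenomicInterval]:
    """Precursor-minus-mature region, per base and per strand, merged.

    Mature arms remove bases only from precursors on the same chrom and
    strand; anything else leaves the precursor untouched.
    """
    prim = _as_intervals(primary)
    mat = _as_intervals(mature)
    by_key: dict[tuple[str, str], list[GenomicInterval]] = {}
    for iv in prim:
        by_key.setdefault((iv.chrom, iv.strand), []).append(iv)
    mat_by_key: dict[tuple[str, str], list[GenomicInterval]] = {}
    for iv in mat:
        mat_by_key.setdefault((iv.chrom, iv.strand), []).append(iv)
    out: list[GenomicInterval] = []
    for key in by_key:
        merged_prim = merge_intervals(by_key[key])
        merged_mat = merge_intervals(mat_by_key.get(key, []))
        out.extend(subtract_intervals(merged_prim, merged_mat))
    return sorted(out)


@dataclass
class AnnotationBundle:
    """All annotation layers plus their strand-aware indexes.

    ``gene_exons`` maps gene id to its merged exon intervals (exons of all
    transcripts of a gene are unioned, since counting is at gene level);
    ``introns`` is the union over transcripts of span-minus-exons.
    Derived members (indexes, the non-mature miRNA set) are built on
    construction.
    """

    gene_exons: dict[str, list[GenomicInterval]]
    gene_biotype: dict[str, str]
    introns: list[GenomicInterval]
    trna: list[GenomicInterval]
    repeats: list[GenomicInterval]
    mirna_primary: list[MirnaFeature] = field(default_factory=list)
    mirna_mature: list[MirnaFeature] = field(default_factory=list)

    exon_index: StrandedIndex = field(init=False, repr=False)
    intron_index: StrandedIndex = field(init=False, repr=False)
    trna_index: StrandedIndex = field(init=False, repr=False)
    repeat_index: StrandedIndex = field(init=False, repr=False)
    mirna_nonmature: list[GenomicInterval] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.exon_index = StrandedIndex(
            (iv, gid) for gid, ivs in self.gene_exons.items() for iv in ivs
        )
        self.intron_index = StrandedIndex(self.introns)
        self.trna_index = StrandedIndex(self.trna)
        self.repeat_index = StrandedIndex(self.repeats)
        self.mirna_nonmature = derive_nonmature(self.mirna_primary, self.mirna_mature)

    @classmethod
    def build(
        cls,
        transcripts: Iterable[TranscriptModel],
        trna: Iterable[GenomicInterval] = (),
        repeats: Iterable[GenomicInterval] = (),
        mirna_primary: Iterable[MirnaFeature] = (),
        mirna_mature: Iterable[MirnaFeature] = (),
    ) -> "AnnotationBundle":
        transcripts = list(transcripts)
        per_gene: dict[str, list[GenomicInterval]] = {}
        biotype: dict[str, str] = {}
        introns: list[GenomicInterval] = []
        for t in transcripts:
            per_gene.setdefault(t.gene_id, []).extend(t.exons)
            biotype.setdefault(t.gene_id, t.biotype)
            introns.extend(derive_introns(t))
        gene_exons = {gid: merge_intervals(ivs) for gid, ivs in per_gene.items()}
        by_key: dict[tuple[str, str], list[GenomicInterval]] = {}
        for iv in introns:
            by_key.setdefault((iv.chrom, iv.strand), []).append(iv)
        merged_introns = sorted(
            iv for key in by_key for iv in merge_intervals(by_key[key])
        )
        return cls(
            gene_exons=gene_exons,
            gene_biotype=biotype,
            introns=merged_introns,
            trna=list(trna),
            repeats=list(repeats),
            mirna_primary=list(mirna_primary),
            mirna_mature=list(mirna_mature),
        )

    # -- serialization: a directory of BED files plus a JSON manifest -------

    def to_dir(self, path: Union[str, Path]) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        exon_rows = sorted(
            (iv, gid) for gid, ivs in self.gene_exons.items() for iv in ivs
        )
        write_bed((iv for iv, _ in exon_rows), path / "exon.bed",
                  [gid for _, gid in exon_rows])
        write_bed(sorted(self.introns), path / "intron.bed")
        write_bed(sorted(self.trna), path / "trna.bed")
        write_bed(sorted(self.repeats), path / "repeat.bed")
        for fname, feats in (
            ("mirna_primary.bed", self.mirna_primary),
            ("mirna_mature.bed", self.mirna_mature),
        ):
            feats = sorted(feats, key=lambda f: f.interval)
            names = [
                "|".join(x or "" for x in (f.accession, f.name, f.derives_from))
                for f in feats
            ]
            write_bed((f.interval for f in feats), path / fname, names)
        manifest = {
            "format": "stakit-annotation-bundle/1",
            "genes": dict(sorted(self.gene_biotype.items())),
            "files": [
                "exon.bed", "intron.bed", "trna.bed", "repeat.bed",
                "mirna_primary.bed", "mirna_mature.bed",
            ],
        }
        (path / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")

    @classmethod
    def from_dir(cls, path: Union[str, Path]) -> "AnnotationBundle":
        path = Path(path)
        manifest = json.loads((path / "manifest.json").read_text())
        gene_exons: dict[str, list[GenomicInterval]] = {}
        with open(path / "exon.bed") as fh:
            for line in fh:
                chrom, start, end, name, _score, strand = line.split("\t")
                gene_exons.setdefault(name, []).append(
                    GenomicInterval(chrom, int(start), int(end), strand.strip())
                )

        def named_bed(fname: str) -> list[MirnaFeature]:
            feats = []
            with open(path / fname) as fh:
                for line in fh:
                    chrom, start, end, name, _score, strand = line.split("\t")
                    acc, nm, der = (name.split("|") + ["", "", ""])[:3]
                    feats.append(
                        MirnaFeature(
                            GenomicInterval(chrom, int(start), int(end), strand.strip()),
                            accession=acc or None,
                            name=nm or None,
                            derives_from=der or None,
                        )
                    )
            return feats

        return cls(
            gene_exons=gene_exons,
            gene_biotype=dict(manifest["genes"]),
            introns=parse_bed(path / "intron.bed"),
            trna=parse_bed(path / "trna.bed"),
            repeats=parse_bed(path / "repeat.bed"),
            mirna_primary=named_bed("mirna_primary.bed"),
            mirna_mature=named_bed("mirna_mature.bed"),
        )


def load_bundle(
    gtf: Union[str, Path],
    trna: Optional[Union[str, Path]] = None,
    repeats: Optional[Union[str, Path]] = None,
    mirna_gff3: Optional[Union[str, Path]] = None,
) -> AnnotationBundle:
    """Build a bundle from annotation files (GTF + optional tRNA/repeat/miRNA).

    The tRNA layer may be either BED or GTF (the exons of every transcript
    are used in the latter case).
    """
    transcripts = parse_gtf(gtf)
    trna_ivs: list[GenomicInterval] = []
    if trna is not None:
        if str(trna).endswith((".gtf", ".gff", ".gff3")):
            trna_ivs = [ex for t in parse_gtf(trna) for ex in t.exons]
        else:
            trna_ivs = parse_bed(trna)
    repeat_ivs = parse_bed(repeats) if repeats is not None else []
    primary: list[MirnaFeature] = []
    mature: list[MirnaFeature] = []
    if mirna_gff3 is not None:
        primary, mature = parse_mirna_gff3(mirna_gff3)
    return AnnotationBundle.build(
        transcripts, trna_ivs, repeat_ivs, primary, mature
    )
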