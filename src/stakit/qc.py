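"""Library quality control: 3'-bias profile, RPM coverage tracks, composition.

A polyadenylation-anchored library primes reverse transcription at the
poly(A) tail, so coverage should pile up at the 3' ends of transcripts.
The gene-body profile makes that visible: per-base depth over each
transcript's exonic body is rescaled to 100 length-percentile bins oriented
5'→3' (bin 100 is the 3' end), summed over transcripts, and normalized to
1.  A 3'-skewed profile is the expected signature of the chemistry; a flat
profile would indicate the tails were not the priming sites.

Coverage tracks are written as stranded bedGraph with values in reads per
million: per-base depth × 10^6 / aligned read total.  The reverse-strand
track is a separate file with positive values; sign flipping is a display
concern.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np

from .annotation import TranscriptModel
from .assign import Alignment, BiotypeSummary, CategoryCounts
from .mirna import MatureCounts
from .preprocess import PreprocessStats

logger = logging.getLogger(__name__)

N_BINS = 100


@dataclass
class GeneBodyProfile:
    """Fraction of aggregated exonic coverage per transcript-length percentile."""

    bins: np.ndarray  # length 100, 5'→3'
    n_transcripts: int = 0

    @property
    def three_prime_mass(self) -> float:
        """Coverage fraction in the 3' half (bins 51-100)."""
        return float(self.bins[N_BINS // 2:].sum())


@dataclass
class CoverageTrack:
    """RPM-normalized per-strand coverage as merged constant-value intervals."""

    forward: dict[str, list[tuple[int, int, float]]]
    reverse: dict[str, list[tuple[int, int, float]]]
    aligned_total: int


def _depth_arrays(
    alignments: Iterable[Alignment],
    chrom_sizes: Optional[dict[str, int]] = None,
) -> dict[tuple[str, str], np.ndarray]:
    """Per-(chrom, strand) depth arrays via difference accumulation."""
    alignments = list(alignments)
    sizes: dict[str, int] = dict(chrom_sizes or {})
    for aln in alignments:
        iv = aln.interval
        sizes[iv.chrom] = max(sizes.get(iv.chrom, 0), iv.end)
    diffs: dict[tuple[str, str], np.ndarray] = {}
    for aln in alignments:
        iv = aln.interval
        if iv.strand == ".":
            raise ValueError(
                f"read {aln.read_id}: strandless alignments cannot be placed "
                "on a strand track"
            )
        key = (iv.chrom, iv.strand)
        if key not in diffs:
            diffs[key] = np.zeros(sizes[iv.chrom] + 1, dtype=np.int64)
        diffs[key][iv.start] += 1
        diffs[key][iv.end] -= 1
    return {key: np.cumsum(d)[:-1] for key, d in diffs.items()}


def gene_body_coverage(
    alignments: Iterable[Alignment],
    transcripts: Iterable[TranscriptModel],
    min_len: int = 100,
) -> GeneBodyProfile:
    """Aggregate 5'→3' exonic coverage profile over all eligible transcripts.

    Transcripts with fewer than ``min_len`` exonic bases are excluded (a
    percentile profile over a very short body is mostly binning noise).
    Only same-strand coverage counts; for minus-strand transcripts the body
    is reversed so bin 100 is always the 3' end.
    """
    transcripts = [t for t in transcripts if t.exonic_length >= min_len]
    depth = _depth_arrays(alignments)
    bins = np.zeros(N_BINS)
    for t in transcripts:
        arr = depth.get((t.chrom, t.strand))
        if arr is None:
            continue
        parts = []
        for ex in t.exons:
            seg = arr[ex.start:min(ex.end, arr.size)].astype(float)
            if seg.size < ex.length:  # zero depth past the last alignment
                seg = np.concatenate([seg, np.zeros(ex.length - seg.size)])
            parts.append(seg)
        body = np.concatenate(parts) if parts else np.zeros(0)
        if body.size == 0 or not body.any():
            continue
        if t.strand == "-":
            body = body[::-1]
        idx = (np.arange(body.size) * N_BINS) // body.size
        bins += np.bincount(idx, weights=body, minlength=N_BINS)
    total = bins.sum()
    if not transcripts or total == 0:
        if not transcripts:
            warnings.warn("gene_body_coverage: no eligible transcript", stacklevel=2)
        return GeneBodyProfile(bins=np.zeros(N_BINS), n_transcripts=len(transcripts))
    return GeneBodyProfile(bins=bins / total, n_transcripts=len(transcripts))


def rpm_tracks(
    alignments: Iterable[Alignment],
    aligned_total: Optional[int] = None,
) -> CoverageTrack:
    """Stranded RPM coverage: per-base depth × 10^6 / aligned_total.

    ``aligned_total`` defaults to the number of alignments given; it must be
    positive.  Only positive-depth runs are emitted, merged into
    constant-value intervals.
    """
    alignments = list(alignments)
    if aligned_total is None:
        aligned_total = len(alignments)
    if aligned_total <= 0:
        raise ValueError("rpm_tracks requires aligned_total > 0")
    scale = 1e6 / aligned_total
    tracks: dict[str, dict[str, list[tuple[int, int, float]]]] = {"+": {}, "-": {}}
    for (chrom, strand), depth in _depth_arrays(alignments).items():
        segs: list[tuple[int, int, float]] = []
        boundaries = np.flatnonzero(np.diff(depth)) + 1
        starts = np.concatenate([[0], boundaries])
        ends = np.concatenate([boundaries, [depth.size]])
        for s, e in zip(starts, ends):
            d = int(depth[s])
            if d > 0:
                segs.append((int(s), int(e), d * scale))
        if segs:
            tracks[strand][chrom] = segs
    return CoverageTrack(
        forward=tracks["+"], reverse=tracks["-"], aligned_total=aligned_total
    )


def write_bedgraph(track: CoverageTrack, out_prefix: Union[str, Path]) -> list[Path]:
    """Write ``<prefix>.fwd.bedGraph`` and ``<prefix>.rev.bedGraph``.

    Deterministic: chromosomes lexicographically sorted, fixed 6-decimal
    values — reruns produce byte-identical files.
    """
    out_prefix = Path(out_prefix)
    paths = []
    for suffix, data in (("fwd", track.forward), ("rev", track.reverse)):
        path = out_prefix.parent / f"{out_prefix.name}.{suffix}.bedGraph"
        with open(path, "w") as fh:
            for chrom in sorted(data):
                for s, e, v in data[chrom]:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:.6f}\n")
        paths.append(path)
    return paths


def track_mass(track: CoverageTrack) -> float:
    """Σ(value × interval length) over both strand tracks.

    Conservation: equals 10^6 × (total aligned bases) / aligned_total.
    """
    return float(
        sum(
            (e - s) * v
            for data in (track.forward, track.reverse)
            for segs in data.values()
            for s, e, v in segs
        )
    )


def composition_report(
    library_id: str = "library",
    preprocess: Optional[PreprocessStats] = None,
    category: Optional[CategoryCounts] = None,
    biotype: Optional[BiotypeSummary] = None,
    mature: Optional[MatureCounts] = None,
) -> dict:
    """Single JSON-ready document combining all per-library summaries.

    Every percentage in the report is recomputable from the raw counts it
    sits next to.  Components carrying a ``library_id`` must agree with the
    report's id.
    """
    for part in (preprocess, category, biotype, mature):
        if part is not None and part.library_id not in (None, library_id):
            raise ValueError(
                f"mismatched library ids: {part.library_id!r} vs {library_id!r}"
            )
    report: dict = {"library_id": library_id}
    if preprocess is not None:
        report["preprocess"] = {
            "reads_in": preprocess.reads_in,
            "reads_with_tail": preprocess.reads_with_tail,
            "reads_out": preprocess.reads_out,
            "fraction_with_tail": (
                preprocess.reads_with_tail / preprocess.reads_in
                if preprocess.reads_in else 0.0
            ),
            "fraction_out": (
                preprocess.reads_out / preprocess.reads_in
                if preprocess.reads_in else 0.0
            ),
        }
    if category is not None:
        report["categories"] = {
            "counts": category.as_dict(),
            "aligned_total": category.aligned_total,
            "fractions": category.fractions(),
        }
    if biotype is not None:
        report["biotypes"] = {
            "counts": dict(sorted(biotype.counts.items())),
            "exon_total": biotype.exon_total,
            "fractions": biotype.fractions(),
        }
    if mature is not None:
        report["mature_mirna"] = {
            "input_reads": mature.input_reads,
            "removed_reads": mature.removed_reads,
            "mature_total": mature.total,
            "n_features_detected": sum(1 for v in mature.counts.values() if v > 0),
        }
    return report


def write_profile(
    profile: GeneBodyProfile, path: Union[str, Path], plot: Optional[Union[str, Path]] = None
) -> None:
    """Write the profile as JSON; optionally render a PNG line plot."""
    Path(path).write_text(
        json.dumps(
            {
                "bins": [float(x) for x in profile.bins],
                "n_transcripts": profile.n_transcripts,
                "three_prime_mass": profile.three_prime_mass,
            },
            indent=2,
        )
        + "\n"
    )
    if plot is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 3.2))
        ax.plot(np.arange(1, N_BINS + 1), profile.bins, lw=1.5)
        ax.set_xlabel("gene body percentile (5'→3')")
        ax.set_ylabel("coverage fraction")
        ax.set_title("gene body coverage")
        fig.tight_layout()
        fig.savefig(plot, dpi=120)
        plt.close(fig)
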