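"""Poly(A)-tail detection, selection and clipping for raw reads.

In a polyadenylation-anchored library every captured molecule carries an
enzymatically added A tail at its 3' end, so the informative insert is the
5' portion of each read and the terminal A run is chemistry, not biology.
Reads whose 3' end shows a sufficiently long A run (more than eight As, i.e.
a run of at least nine) are selected, the run is clipped away, and inserts
shorter than the downstream aligner's minimum match length (18 nt) are
dropped so they never reach alignment.

Quality strings are clipped in lockstep with bases; no quality-based
trimming is performed.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterator, Optional, Union

from Bio.SeqIO.QualityIO import FastqGeneralIterator

DEFAULT_MIN_TAIL = 9
DEFAULT_MIN_INSERT = 18


class FastqFormatError(ValueError):
    """Malformed FASTQ input (bad record structure or quality length)."""


@dataclass(frozen=True)
class RawRead:
    """A single FASTQ read: id, bases over {A,C,G,T,N}, Phred+33 qualities."""

    read_id: str
    sequence: str
    qualities: str

    def __post_init__(self) -> None:
        if len(self.sequence) == 0:
            raise FastqFormatError(f"read {self.read_id!r}: empty sequence")
        if len(self.sequence) != len(self.qualities):
            raise FastqFormatError(
                f"read {self.read_id!r}: sequence length {len(self.sequence)} "
                f"!= quality length {len(self.qualities)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class TailCall:
    """Decomposition of a read into a 5' insert and a 3' poly(A) tail."""

    tail_length: int
    insert_length: int
    passed_tail_filter: bool
    passed_insert_filter: bool


@dataclass
class PreprocessStats:
    """Per-library tail-selection bookkeeping."""

    reads_in: int = 0
    reads_with_tail: int = 0
    reads_out: int = 0
    tail_length_histogram: dict[int, int] = field(default_factory=dict)
    library_id: Optional[str] = None

    def as_dict(self) -> dict:
        return {
            "reads_in": self.reads_in,
            "reads_with_tail": self.reads_with_tail,
            "reads_out": self.reads_out,
            "tail_length_histogram": {
                str(k): v for k, v in sorted(self.tail_length_histogram.items())
            },
            "library_id": self.library_id,
        }


def detect_tail(
    read: RawRead,
    min_tail: int = DEFAULT_MIN_TAIL,
    max_interruptions: int = 0,
    min_insert: int = DEFAULT_MIN_INSERT,
) -> TailCall:
    """Measure the 3'-terminal poly(A) run of a read.

    The tail is the maximal run of ``A`` at the 3' end.  Up to
    ``max_interruptions`` isolated non-A bases are tolerated inside the run
    (each must be followed 5'-ward by another A, so an interruption can never
    sit at the 5' boundary of the tail).  ``N`` never counts as ``A``.

    The default ``min_tail=9`` encodes the "more than eight As" selection
    rule; ``min_insert`` mirrors the aligner's minimum match length so the
    insert filter can be reported alongside the tail filter.
    """
    if min_tail < 1:
        raise ValueError("min_tail must be >= 1")
    seq = read.sequence
    i = len(seq) - 1
    tail = 0
    interruptions = 0
    while i >= 0:
        if seq[i] == "A":
            tail += 1
            i -= 1
        elif (
            interruptions < max_interruptions
            and i >= 1
            and seq[i - 1] == "A"
            and tail > 0
        ):
            # isolated mismatch inside the run; clipped with the tail
            interruptions += 1
            tail += 1
            i -= 1
        else:
            break
    insert = len(seq) - tail
    passed_tail = tail >= min_tail
    return TailCall(
        tail_length=tail,
        insert_length=insert,
        passed_tail_filter=passed_tail,
        passed_insert_filter=passed_tail and insert >= min_insert,
    )


def clip_tail(
    read: RawRead, call: TailCall, min_insert: int = DEFAULT_MIN_INSERT
) -> Optional[RawRead]:
    """Return the 5' insert of a tail-positive read, or None.

    None is returned when the read failed the tail filter or the remaining
    insert is shorter than ``min_insert``.  Sequence and qualities are
    truncated together.  With ``max_interruptions=0`` the returned insert
    never ends in ``A`` (the tail run was maximal), so re-processing an
    already clipped stream yields nothing — intentionally.
    """
    if not call.passed_tail_filter or call.insert_length < min_insert:
        return None
    n = call.insert_length
    return RawRead(read.read_id, read.sequence[:n], read.qualities[:n])


def _open_maybe_gz(path: Union[str, Path], mode: str) -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode + "t")
    return open(path, mode)


def iter_fastq(handle: IO[str]) -> Iterator[RawRead]:
    """Yield RawRead records from a FASTQ text stream.

    Malformed records are reported with the index of the offending record.
    """
    it = FastqGeneralIterator(handle)
    idx = 0
    while True:
        try:
            rec = next(it)
        except StopIteration:
            return
        except ValueError as exc:
            raise FastqFormatError(f"malformed FASTQ record {idx}: {exc}") from exc
        title, seq, qual = rec
        try:
            yield RawRead(title.split()[0], seq.upper(), qual)
        except FastqFormatError as exc:
            raise FastqFormatError(f"FASTQ record {idx}: {exc}") from exc
        idx += 1


def write_fastq_record(handle: IO[str], read: RawRead) -> None:
    handle.write(f"@{read.read_id}\n{read.sequence}\n+\n{read.qualities}\n")


def process_fastq(
    in_path: Union[str, Path],
    out_path: Union[str, Path],
    min_tail: int = DEFAULT_MIN_TAIL,
    min_insert: int = DEFAULT_MIN_INSERT,
    max_interruptions: int = 0,
    library_id: Optional[str] = None,
) -> PreprocessStats:
    """Select tail-positive reads, clip the tails, and write the inserts.

    The output contains exactly the clipped inserts of reads passing both
    the tail filter and the insert-length filter, with read ids preserved.
    Gzip is used for either side when the filename ends in ``.gz``.
    """
    stats = PreprocessStats(library_id=library_id)
    with _open_maybe_gz(in_path, "r") as fin, _open_maybe_gz(out_path, "w") as fout:
        for read in iter_fastq(fin):
            stats.reads_in += 1
            call = detect_tail(
                read,
                min_tail=min_tail,
                max_interruptions=max_interruptions,
                min_insert=min_insert,
            )
            if not call.passed_tail_filter:
                continue
            stats.reads_with_tail += 1
            stats.tail_length_histogram[call.tail_length] = (
                stats.tail_length_histogram.get(call.tail_length, 0) + 1
            )
            insert = clip_tail(read, call, min_insert=min_insert)
            if insert is None:
                continue
            stats.reads_out += 1
            write_fastq_record(fout, insert)
    return stats


def write_stats(stats: PreprocessStats, path: Union[str, Path]) -> None:
    Path(path).write_text(json.dumps(stats.as_dict(), indent=2) + "\n")
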