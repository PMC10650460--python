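"""Small-RNA FASTQ ingestion, length/quality filtering and read collapsing.

Adapter trimming is assumed already done upstream; the structural filter is
the 15–30 nt analysis window conventional for mature miRNA reads, plus a
configurable mean-Phred floor. Identical sequences are collapsed into counted
unique reads before isomiR decomposition.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio.SeqIO.QualityIO import FastqGeneralIterator

PHRED_OFFSET = 33
PHRED_MAX = 60


class FastqParseError(ValueError):
    """Truncated or malformed FASTQ input."""


@dataclass(frozen=True)
class ReadRecord:
    read_id: str
    sequence: str
    quality: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.quality):
            raise ValueError(
                f"read {self.read_id!r}: sequence/quality length mismatch"
            )
        if any(q < 0 or q > PHRED_MAX for q in self.quality):
            raise ValueError(f"read {self.read_id!r}: Phred value outside [0, {PHRED_MAX}]")

    @property
    def mean_quality(self) -> float:
        return sum(self.quality) / len(self.quality) if self.quality else 0.0


@dataclass(frozen=True)
class QCParams:
    """Filtering thresholds; reads kept iff min_len <= len <= max_len and
    mean Phred >= min_mean_q."""

    min_len: int = 15
    max_len: int = 30
    min_mean_q: float = 20.0

    def __post_init__(self) -> None:
        if not (0 < self.min_len <= self.max_len):
            raise ValueError("require 0 < min_len <= max_len")


@dataclass(frozen=True)
class CollapsedRead:
    sequence: str
    count: int

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("collapsed count must be >= 1")


def read_fastq(path: str | Path) -> Iterator[ReadRecord]:
    """Stream Phred+33 FASTQ records in file order, T→U normalized."""
    path = Path(path)
    with open(path) as fh:
        it = FastqGeneralIterator(fh)
        index = 0
        while True:
            try:
                title, seq, qual = next(it)
            except StopIteration:
                return
            except ValueError as exc:
                raise FastqParseError(f"{path}: record {index}: {exc}") from exc
            read_id = title.split()[0] if title else f"read{index}"
            yield ReadRecord(
                read_id=read_id,
                sequence=seq.upper().replace("T", "U"),
                quality=tuple(ord(c) - PHRED_OFFSET for c in qual),
            )
            index += 1


def write_fastq(records: Iterable[ReadRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            qual = "".join(chr(q + PHRED_OFFSET) for q in rec.quality)
            fh.write(f"@{rec.read_id}\n{rec.sequence}\n+\n{qual}\n")


def filter_reads(
    reads: Iterable[ReadRecord], params: QCParams = QCParams()
) -> tuple[list[ReadRecord], dict[str, int]]:
    """Partition reads into kept vs rejected-by-reason; stats are exact.

    Returns (kept, stats) where stats counts {kept, too_short, too_long,
    low_quality} and sums to the input size. Length is checked before
    quality, so a short low-quality read counts as too_short.
    """
    kept: list[ReadRecord] = []
    stats = {"kept": 0, "too_short": 0, "too_long": 0, "low_quality": 0}
    for rec in reads:
        n = len(rec.sequence)
        if n < params.min_len:
            stats["too_short"] += 1
        elif n > params.max_len:
            stats["too_long"] += 1
        elif rec.mean_quality < params.min_mean_q:
            stats["low_quality"] += 1
        else:
            stats["kept"] += 1
            kept.append(rec)
    return kept, stats


def collapse(reads: Iterable[ReadRecord]) -> list[CollapsedRead]:
    """Collapse identical sequences into counted unique reads.

    Deterministic order: count descending, then lexicographic sequence.
    Total count is conserved.
    """
    counts = Counter(rec.sequence for rec in reads)
    return [
        CollapsedRead(seq, n)
        for seq, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]


def write_collapsed_fasta(collapsed: Iterable[CollapsedRead], path: str | Path) -> None:
    """Write collapsed reads in the ``>seq{i}_x{count}`` count-suffix dialect."""
    with open(path, "w") as fh:
        for i, cr in enumerate(collapsed, start=1):
            fh.write(f">seq{i}_x{cr.count}\n{cr.sequence}\n")


def read_collapsed_fasta(path: str | Path) -> list[CollapsedRead]:
    """Read the count-suffix dialect back (inverse of write_collapsed_fasta)."""
    out: list[CollapsedRead] = []
    header = None
    seq_parts: list[str] = []

    def flush() -> None:
        if header is None:
            return
        try:
            count = int(header.rsplit("_x", 1)[1])
        except (IndexError, ValueError):
            count = 1
        out.append(CollapsedRead("".join(seq_parts).upper().replace("T", "U"), count))

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                flush()
                header = line[1:].split()[0]
                seq_parts = []
            elif line:
                seq_parts.append(line)
        flush()
    return out


def write_qc_report(stats: dict[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("reason\tcount\n")
        for reason, n in stats.items():
            fh.write(f"{reason}\t{n}\n")
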