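"""Sequence I/O: FASTA/FASTQ readers and writers plus per-sample read QC.

FASTQ qualities are Phred+33 only; files may be plain or gzip-compressed
(detected from the magic bytes, not the extension).  Paired-end files are
treated as two independent single-end streams — all downstream accounting
is in reads, not pairs.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Iterator

from Bio import SeqIO

__all__ = [
    "ReadRecord",
    "QCSummary",
    "read_fastq",
    "read_fasta",
    "write_fasta",
    "write_fastq",
    "qc_summary",
    "write_qc_table",
]

#: Highest Phred score plausibly produced by Phred+33 instruments; anything
#: above it almost certainly means the file is Phred+64 encoded.
_MAX_PLAUSIBLE_PHRED = 45


@dataclass(frozen=True)
class ReadRecord:
    """A single sequencing read.

    ``truth_species`` records simulation provenance (which genome the read
    was drawn from) and is None for real data.
    """

    read_id: str
    sequence: str
    qualities: tuple[int, ...] | None = None
    truth_species: str | None = None

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"read {self.read_id!r}: empty sequence")
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise ValueError(
                f"read {self.read_id!r}: {len(self.qualities)} quality values "
                f"for {len(self.sequence)} bases"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class QCSummary:
    """Per-sample read statistics: totals, Q20/Q30 and GC fractions.

    Quality fractions are None when the stream carried no quality scores.
    N bases are excluded from both numerator and denominator of the GC
    fraction.
    """

    n_reads: int
    n_bases: int
    q20_fraction: float | None
    q30_fraction: float | None
    gc_fraction: float

    def __post_init__(self) -> None:
        for name in ("q20_fraction", "q30_fraction", "gc_fraction"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if (
            self.q20_fraction is not None
            and self.q30_fraction is not None
            and self.q30_fraction > self.q20_fraction + 1e-12
        ):
            raise ValueError("q30_fraction exceeds q20_fraction")


def _open_text(path: str | Path) -> IO[str]:
    path = Path(path)
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fastq(path: str | Path) -> Iterator[ReadRecord]:
    """Stream ReadRecords from a (possibly gzipped) Phred+33 FASTQ file.

    Raises ValueError naming the record index on a malformed 4-line block,
    and rejects quality strings that look Phred+64 encoded.
    """
    with _open_text(path) as handle:
        parser = SeqIO.parse(handle, "fastq")
        index = 0
        while True:
            try:
                rec = next(parser)
            except StopIteration:
                return
            except ValueError as exc:
                raise ValueError(
                    f"{path}: malformed FASTQ at record {index}: {exc}"
                ) from exc
            quals = tuple(rec.letter_annotations["phred_quality"])
            if quals and max(quals) > _MAX_PLAUSIBLE_PHRED:
                raise ValueError(
                    f"{path}: record {rec.id}: Phred score {max(quals)} > "
                    f"{_MAX_PLAUSIBLE_PHRED}; input looks Phred+64 encoded, "
                    "only Phred+33 is supported"
                )
            yield ReadRecord(rec.id, str(rec.seq).upper(), quals)
            index += 1


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into a list of (id, uppercased sequence).

    Duplicate identifiers are an error (all duplicates are listed).
    """
    records: list[tuple[str, str]] = []
    seen: dict[str, int] = {}
    with _open_text(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            seen[rec.id] = seen.get(rec.id, 0) + 1
            records.append((rec.id, str(rec.seq).upper()))
    dups = sorted(k for k, v in seen.items() if v > 1)
    if dups:
        raise ValueError(f"{path}: duplicate FASTA identifiers: {', '.join(dups)}")
    return records


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]]) -> None:
    """Write (id, sequence) pairs as FASTA wrapped at 60 columns."""
    with open(path, "wt") as handle:
        for name, seq in records:
            handle.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                handle.write(seq[i : i + 60] + "\n")


def write_fastq(path: str | Path, reads: Iterable[ReadRecord]) -> None:
    """Write reads as Phred+33 FASTQ (gzipped when the path ends in .gz).

    Reads without qualities are written at a constant Q30.
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as handle:  # type: ignore[operator]
        for read in reads:
            quals = read.qualities or (30,) * len(read)
            qline = "".join(chr(q + 33) for q in quals)
            handle.write(f"@{read.read_id}\n{read.sequence}\n+\n{qline}\n")


def qc_summary(reads: Iterable[ReadRecord]) -> QCSummary:
    """Summarise a read stream: counts, Q20/Q30 fractions, GC fraction.

    Quality fractions are reported only when every read carries qualities.
    An empty stream (zero bases) is an error.
    """
    n_reads = n_bases = 0
    gc = acgt = 0
    q20 = q30 = 0
    all_have_quals = True
    for read in reads:
        n_reads += 1
        n_bases += len(read)
        seq = read.sequence
        gc += seq.count("G") + seq.count("C")
        acgt += sum(seq.count(b) for b in "ACGT")
        if read.qualities is None:
            all_have_quals = False
        elif all_have_quals:
            q20 += sum(q >= 20 for q in read.qualities)
            q30 += sum(q >= 30 for q in read.qualities)
    if n_bases == 0:
        raise ValueError("qc_summary: zero bases in input")
    if acgt == 0:
        raise ValueError("qc_summary: no unambiguous (A/C/G/T) bases in input")
    return QCSummary(
        n_reads=n_reads,
        n_bases=n_bases,
        q20_fraction=q20 / n_bases if all_have_quals else None,
        q30_fraction=q30 / n_bases if all_have_quals else None,
        gc_fraction=gc / acgt,
    )


def write_qc_table(path: str | Path, summaries: dict[str, QCSummary]) -> None:
    """Write per-sample QC summaries as a TSV with one row per sample."""

    def fmt(v: float | None) -> str:
        return "" if v is None else f"{v:.6f}"

    with open(path, "wt") as handle:
        handle.write("sample\tn_reads\tn_bases\tq20_fraction\tq30_fraction\tgc_fraction\n")
        for sample, s in summaries.items():
            handle.write(
                f"{sample}\t{s.n_reads}\t{s.n_bases}\t{fmt(s.q20_fraction)}\t"
                f"{fmt(s.q30_fraction)}\t{fmt(s.gc_fraction)}\n"
            )
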