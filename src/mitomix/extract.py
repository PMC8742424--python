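"""Step S1: partition shotgun reads into mitochondrial and unmapped.

A read is "mitochondrial" when it shares at least ``min_seed_hits`` exact
k-mers with some panel genome on a common diagonal and the ungapped
extension along that diagonal reaches ``min_span`` bases at
``min_identity`` identity.  Both the read and its reverse complement are
queried against the forward-strand index.

This seed-and-extend rule stands in for a BLASTN search of the panel at a
permissive e-value: for 150 bp reads against a ~0.24 Mb panel, identity
>= 0.80 over a span >= 60 is a comparably permissive operating point.
Reads are *partitioned*, not assigned — a read hitting several species
still counts once here; species assignment happens after mapping (S4).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from ._align import N_BYTE, best_ungapped_segment, encode, revcomp
from .refdb import ReferenceDB
from .seqio import ReadRecord

__all__ = ["ClassifierParams", "ReadHit", "ExtractionResult", "classify_read", "extract_mito"]


@dataclass(frozen=True)
class ClassifierParams:
    """Seed-and-extend classifier thresholds.

    k             : exact seed length (matches the database index)
    min_seed_hits : seeds required on one (species, diagonal) candidate
    min_identity  : identity of the best ungapped extension
    min_span      : length of the best ungapped extension, bases
    """

    k: int = 21
    min_seed_hits: int = 1
    min_identity: float = 0.80
    min_span: int = 60

    def __post_init__(self) -> None:
        if not 0.0 < self.min_identity <= 1.0:
            raise ValueError("min_identity must be in (0, 1]")
        if self.min_seed_hits < 1 or self.min_span < 1:
            raise ValueError("min_seed_hits and min_span must be positive")


@dataclass(frozen=True)
class ReadHit:
    """Best panel hit for one read."""

    species_id: str
    identity: float
    span: int
    strand: str


@dataclass
class ExtractionResult:
    """Partition of the input reads (order preserved within each part).

    mito_fraction is None on empty input; n_too_short counts reads shorter
    than the seed length (classified unmapped with a warning counter rather
    than an error).
    """

    mito_reads: list[ReadRecord]
    unmapped_reads: list[ReadRecord]
    mito_fraction: float | None
    n_too_short: int = 0

    @property
    def n_input(self) -> int:
        return len(self.mito_reads) + len(self.unmapped_reads)


def _candidates(
    seq: str, db: ReferenceDB, k: int
) -> dict[tuple[str, int], int]:
    """Seed counts per (species, diagonal); diagonals modulo genome length."""
    counts: dict[tuple[str, int], int] = {}
    index = db.index
    lengths = {s: len(g) for s, g in db.genomes.items()}
    for i in range(len(seq) - k + 1):
        hits = index.get(seq[i : i + k])
        if not hits:
            continue
        for species, pos, _ in hits:
            diag = (pos - i) % lengths[species]
            key = (species, diag)
            counts[key] = counts.get(key, 0) + 1
    return counts


def _extend(
    read_arr: np.ndarray, db: ReferenceDB, species: str, diag: int
) -> tuple[float, int]:
    """Ungapped +1/-1 extension of a read along one diagonal; returns
    (identity, span) of the best-scoring segment."""
    genome = db.genomes[species]
    L = len(genome)
    rl = read_arr.size
    ext = db.extended_array(species)
    if genome.circular:
        window = ext[diag : diag + rl]
    else:
        window = np.full(rl, 0, dtype=np.uint8)
        lo = max(diag, 0)
        hi = min(diag + rl, L)
        if hi > lo:
            window[lo - diag : hi - diag] = ext[lo:hi]
    if window.size < rl:  # circular genome shorter than the read
        padded = np.zeros(rl, dtype=np.uint8)
        padded[: window.size] = window
        window = padded
    match = (window == read_arr) & (window != N_BYTE) & (read_arr != N_BYTE)
    start, end, n_match = best_ungapped_segment(match)
    span = end - start
    identity = n_match / span if span else 0.0
    return identity, span


def classify_read(
    read: ReadRecord, db: ReferenceDB, params: ClassifierParams | None = None
) -> ReadHit | None:
    """Best panel hit for a read, or None when nothing passes the thresholds.

    Both orientations are seeded; every (species, diagonal) candidate with
    enough seeds is extended ungapped; among candidates passing both the
    span and identity thresholds the winner has the highest identity, ties
    broken by longer span then lexicographic species id.  Reads shorter
    than k cannot be seeded and return None.
    """
    if params is None:
        params = ClassifierParams(k=db.k)
    if params.k != db.k:
        raise ValueError(f"params.k={params.k} does not match database k={db.k}")
    if len(read) < params.k:
        return None
    best: ReadHit | None = None
    for strand, seq in (("+", read.sequence), ("-", revcomp(read.sequence))):
        cands = _candidates(seq, db, params.k)
        read_arr = encode(seq)
        for (species, diag), n_seeds in sorted(cands.items()):
            if n_seeds < params.min_seed_hits:
                continue
            identity, span = _extend(read_arr, db, species, diag)
            if span < params.min_span or identity < params.min_identity:
                continue
            if (
                best is None
                or identity > best.identity
                or (identity == best.identity and species < best.species_id)
            ):
                best = ReadHit(species_id=species, identity=identity, span=span, strand=strand)
    return best


def extract_mito(
    reads: Iterable[ReadRecord],
    db: ReferenceDB,
    params: ClassifierParams | None = None,
) -> ExtractionResult:
    """Partition a read stream by classify_read, preserving input order.

    Every input read lands in exactly one of the two output lists;
    mito_fraction is their ratio (None for empty input).
    """
    if params is None:
        params = ClassifierParams(k=db.k)
    mito: list[ReadRecord] = []
    unmapped: list[ReadRecord] = []
    n_short = 0
    for read in reads:
        if len(read) < params.k:
            n_short += 1
            unmapped.append(read)
            continue
        if classify_read(read, db, params) is not None:
            mito.append(read)
        else:
            unmapped.append(read)
    total = len(mito) + len(unmapped)
    fraction = len(mito) / total if total else None
    return ExtractionResult(
        mito_reads=mito,
        unmapped_reads=unmapped,
        mito_fraction=fraction,
        n_too_short=n_short,
    )
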