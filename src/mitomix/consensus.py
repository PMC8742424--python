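"""Step S2: reference-guided consensus of each species' sample mitogenome.

Public reference mitogenomes come from one individual; the animals in a
sample differ from them by intra-specific variation.  To quantify against
the *sample's* genomes rather than the database's, each species' reads are
piled up on its reference and a majority-vote consensus is called, falling
back to the reference base wherever evidence is thin.  The model is
substitution-only: the consensus has exactly the reference length, which
keeps a single circular coordinate system for mapping.

Placement uses banded end-to-end alignment of the read against the (virtually
extended) reference with band = ceil(band_frac * read_length): alignments
needing more than that many edits are rejected, which keeps reads of other
panel species out of the pileup at realistic panel divergences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import edlib
import numpy as np

from ._align import parse_cigar, revcomp
from .refdb import Mitogenome, ReferenceDB
from .seqio import ReadRecord

__all__ = ["Pileup", "ConsensusGenome", "pileup_reads", "call_consensus", "assemble_all"]

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}
_BYTE_TO_IDX = np.full(256, 255, dtype=np.uint8)
for _b, _i in _BASE_INDEX.items():
    _BYTE_TO_IDX[ord(_b)] = _i


@dataclass
class Pileup:
    """Per-position A/C/G/T counts over a reference coordinate system.

    ``counts`` has shape (reference length, 4); coverage at a position is
    the row sum.  Positions are 0-based and circular genomes wrap modulo
    the length.
    """

    species_id: str
    counts: np.ndarray
    n_placed: int = 0

    @property
    def coverage(self) -> np.ndarray:
        return self.counts.sum(axis=1)


@dataclass
class ConsensusGenome:
    """An assembled (consensus) mitogenome plus its supporting evidence.

    n_corrected_sites is the Hamming distance between consensus and
    reference — the number of intra-specific variants recovered.
    """

    genome: Mitogenome
    coverage: np.ndarray
    n_corrected_sites: int


def _seed_diagonals(seq: str, index: dict[str, list[int]], k: int, L: int) -> list[int]:
    """Distinct reference diagonals sharing an exact k-mer with the read."""
    diags: set[int] = set()
    for i in range(len(seq) - k + 1):
        for pos in index.get(seq[i : i + k], ()):
            diags.add((pos - i) % L)
    return sorted(diags)


def _cluster_diagonals(diags: list[int], span: int) -> list[tuple[int, int]]:
    clusters = []
    lo = hi = diags[0]
    for d in diags[1:]:
        if d - hi <= span:
            hi = d
        else:
            clusters.append((lo, hi))
            lo = hi = d
    clusters.append((lo, hi))
    return clusters


def pileup_reads(
    mito_reads: Iterable[ReadRecord],
    reference: Mitogenome,
    band_frac: float = 0.1,
    min_identity: float = 0.80,
    seed_k: int = 21,
) -> Pileup:
    """Pile mitochondrial reads onto a single reference.

    Each read is seeded by exact ``seed_k``-mers against this reference in
    both orientations, then aligned end-to-end in a window around each
    seeded diagonal with band = ceil(band_frac * read_length).  The best
    accepted placement contributes one count per aligned base at its
    reference position (modulo length for circular references).  Reads with
    no seed, no placement within the band, or identity below
    ``min_identity`` are skipped; an empty pileup is a valid result.

    Because the consensus model is substitution-only, an ungapped placement
    is preferred whenever it achieves the banded edit distance — unit-cost
    alignment otherwise breaks ties arbitrarily between two substitutions
    and an insertion/deletion pair, which would punch spurious holes in the
    coverage.
    """
    L = len(reference)
    target = reference.sequence * 2 if reference.circular else reference.sequence
    index: dict[str, list[int]] = {}
    refseq = (
        reference.sequence + reference.sequence[: seed_k - 1]
        if reference.circular
        else reference.sequence
    )
    for i in range(len(refseq) - seed_k + 1):
        kmer = refseq[i : i + seed_k]
        if "N" not in kmer:
            index.setdefault(kmer, []).append(i % L)
    counts = np.zeros((L, 4), dtype=np.int32)
    n_placed = 0
    for read in mito_reads:
        rl = len(read)
        if rl < seed_k:
            continue
        band = math.ceil(band_frac * rl)
        best = None  # (dist, window_lo, result, seq)
        for seq in (read.sequence, revcomp(read.sequence)):
            diags = _seed_diagonals(seq, index, seed_k, L)
            if not diags:
                continue
            for dlo, dhi in _cluster_diagonals(diags, rl):
                lo = dlo - band
                if lo < 0:
                    lo += L if reference.circular else -lo  # clamp to 0 when linear
                hi = min(dhi + rl + band, len(target))
                if reference.circular and hi <= lo:
                    hi = lo + (dhi - dlo) + rl + 2 * band
                res = edlib.align(seq, target[lo:hi], mode="HW", task="path", k=band)
                dist = res["editDistance"]
                if dist < 0 or 1.0 - dist / rl < min_identity:
                    continue
                if best is None or dist < best[0]:
                    best = (dist, lo, hi, res, seq)
            if best is not None and best[0] == 0:
                break
        if best is None:
            continue
        dist, window_lo, window_hi, res, seq = best
        n_placed += 1
        seq_idx = _BYTE_TO_IDX[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
        # prefer an ungapped placement achieving the same edit distance
        window_arr = np.frombuffer(
            target[window_lo:window_hi].encode("ascii"), dtype=np.uint8
        )
        seq_arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        if window_arr.size >= rl:
            offsets = np.lib.stride_tricks.sliding_window_view(window_arr, rl)
            hamming = (offsets != seq_arr[None, :]).sum(axis=1)
            best_offset = int(np.argmin(hamming))
            if int(hamming[best_offset]) == dist:
                positions = np.arange(window_lo + best_offset, window_lo + best_offset + rl) % L
                valid = seq_idx != 255
                np.add.at(counts, (positions[valid], seq_idx[valid]), 1)
                continue
        start = window_lo + res["locations"][0][0]
        tpos, qpos = start, 0
        for n, op in parse_cigar(res["cigar"]):
            if op in "=XM":
                bidx = seq_idx[qpos : qpos + n]
                positions = np.arange(tpos, tpos + n) % L
                valid = bidx != 255
                np.add.at(counts, (positions[valid], bidx[valid]), 1)
                tpos += n
                qpos += n
            elif op == "I":
                qpos += n
            elif op == "D":
                tpos += n
    return Pileup(species_id=reference.species_id, counts=counts, n_placed=n_placed)


def call_consensus(
    pileup: Pileup, reference: Mitogenome, min_cov: int = 3
) -> ConsensusGenome:
    """Majority-vote consensus with reference fallback.

    A position takes the majority base when coverage >= min_cov, the top
    base holds at least half the coverage, and the top base is unique;
    every other position (low coverage, ties) keeps the reference base.
    min_cov = 3 stops a lone sequencing error from flipping a site.
    """
    L = len(reference)
    if pileup.counts.shape != (L, 4):
        raise ValueError("pileup shape does not match reference length")
    counts = pileup.counts
    cov = counts.sum(axis=1)
    top = counts.max(axis=1)
    argmax = counts.argmax(axis=1)
    tie = (counts == top[:, None]).sum(axis=1) > 1
    use_majority = (cov >= min_cov) & (2 * top >= cov) & ~tie & (top > 0)
    ref_arr = np.frombuffer(reference.sequence.encode("ascii"), dtype=np.uint8)
    base_bytes = np.frombuffer(_BASES.encode("ascii"), dtype=np.uint8)
    cons_arr = np.where(use_majority, base_bytes[argmax], ref_arr)
    consensus = cons_arr.tobytes().decode("ascii")
    n_corrected = int((cons_arr != ref_arr).sum())
    genome = Mitogenome(
        species_id=reference.species_id,
        sequence=consensus,
        accession=None,
        circular=reference.circular,
    )
    return ConsensusGenome(genome=genome, coverage=cov, n_corrected_sites=n_corrected)


def assemble_all(
    mito_reads: list[ReadRecord],
    db: ReferenceDB,
    band_frac: float = 0.1,
    min_identity: float = 0.80,
    min_cov: int = 3,
) -> dict[str, ConsensusGenome]:
    """Consensus for every panel species from the same extracted read pool.

    Reads may contribute to several species' pileups; species assignment is
    deliberately deferred to the unique-mapping step (S4).  Deterministic
    given its inputs.
    """
    out: dict[str, ConsensusGenome] = {}
    for species in db.species_ids:
        reference = db.genomes[species]
        pile = pileup_reads(
            mito_reads, reference, band_frac=band_frac, min_identity=min_identity
        )
        out[species] = call_consensus(pile, reference, min_cov=min_cov)
    return out
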