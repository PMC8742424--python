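"""Reference mitogenome registry, k-mer index and sequence-distance utilities.

The registry plays the role of the searchable reference database a
practitioner would build with ``makeblastdb``: a panel of complete
mitogenomes (one per species), indexed by exact k-mers on the forward
strand.  Reverse-complement handling happens on the read side — the
classifier queries both orientations — which halves the index size.

Distances are plain p-distances (proportion of differing sites among
comparable columns), with no multiple-substitution correction: mitogenome
panels of food species are diverged enough (real panels span roughly
0.14-0.49) that the uncorrected proportion is the conventional statistic.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field

import edlib
import numpy as np
import pandas as pd

from ._align import cigar_to_gapped, encode

__all__ = [
    "Mitogenome",
    "ReferenceDB",
    "DistanceReport",
    "AlignmentError",
    "build_db",
    "load_panel",
    "p_distance",
    "anchored_align",
    "distance_report",
]

_ALPHABET = set("ACGTN")


class AlignmentError(RuntimeError):
    """Raised when a pair of sequences cannot be aligned by anchor chaining."""


@dataclass(frozen=True)
class Mitogenome:
    """One mitochondrial genome with a species label.

    Mammalian and avian mitogenomes are circular molecules of ~16-17 kb;
    ``circular`` controls whether windows and read placements may span the
    sequence origin.
    """

    species_id: str
    sequence: str
    accession: str | None = None
    circular: bool = True

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"{self.species_id}: empty sequence")
        extra = set(self.sequence) - _ALPHABET
        if extra:
            raise ValueError(
                f"{self.species_id}: sequence contains non-ACGTN symbols {sorted(extra)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ReferenceDB:
    """A panel of reference mitogenomes plus a forward-strand k-mer index.

    ``index`` maps each k-mer to its occurrences as (species_id, position,
    strand) with positions 0-based modulo the genome length; circular
    genomes are indexed across the origin.
    """

    genomes: dict[str, Mitogenome]
    k: int
    index: dict[str, list[tuple[str, int, str]]]
    _extended: dict[str, str] = field(default_factory=dict, repr=False)
    _extended_arr: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    @property
    def species_ids(self) -> list[str]:
        return sorted(self.genomes)

    def extended_sequence(self, species_id: str) -> str:
        """Genome sequence virtually extended past the origin (doubled when
        circular) so any window of up to the genome length is contiguous."""
        if species_id not in self._extended:
            g = self.genomes[species_id]
            self._extended[species_id] = g.sequence * 2 if g.circular else g.sequence
        return self._extended[species_id]

    def extended_array(self, species_id: str) -> np.ndarray:
        if species_id not in self._extended_arr:
            self._extended_arr[species_id] = encode(self.extended_sequence(species_id))
        return self._extended_arr[species_id]


def build_db(genomes: list[Mitogenome], k: int = 21) -> ReferenceDB:
    """Index every length-k window of every genome on the forward strand.

    k must be odd (so a k-mer is never its own reverse complement) and at
    most 31.  Windows containing N are skipped; circular genomes contribute
    exactly L windows via virtual extension by k-1 bases past the origin.
    """
    if k % 2 == 0 or not 1 <= k <= 31:
        raise ValueError(f"k must be odd and in [1, 31], got {k}")
    seen: set[str] = set()
    index: dict[str, list[tuple[str, int, str]]] = {}
    registry: dict[str, Mitogenome] = {}
    for g in genomes:
        if g.species_id in seen:
            raise ValueError(f"duplicate species_id {g.species_id!r}")
        seen.add(g.species_id)
        registry[g.species_id] = g
        L = len(g)
        seq = g.sequence + g.sequence[: k - 1] if g.circular else g.sequence
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if "N" in kmer:
                continue
            index.setdefault(kmer, []).append((g.species_id, i % L, "+"))
    return ReferenceDB(genomes=registry, k=k, index=index)


def load_panel(
    fasta_path, table_path=None, *, circular: bool = True
) -> list[Mitogenome]:
    """Load a reference panel from FASTA plus an optional species table.

    The TSV table maps FASTA record ids to species labels with columns
    ``species_id``, ``accession``, ``fasta_id``; without a table the FASTA
    ids themselves serve as species ids.
    """
    from .seqio import read_fasta

    records = dict(read_fasta(fasta_path))
    if table_path is None:
        return [
            Mitogenome(name, seq, circular=circular) for name, seq in records.items()
        ]
    table = pd.read_csv(table_path, sep="\t", dtype=str)
    required = {"species_id", "fasta_id"}
    if not required.issubset(table.columns):
        raise ValueError(f"species table must have columns {sorted(required)}")
    genomes = []
    for row in table.itertuples(index=False):
        if row.fasta_id not in records:
            raise ValueError(f"species table entry {row.fasta_id!r} not in FASTA")
        genomes.append(
            Mitogenome(
                species_id=row.species_id,
                sequence=records[row.fasta_id],
                accession=getattr(row, "accession", None),
                circular=circular,
            )
        )
    return genomes


def p_distance(seq_a: str, seq_b: str) -> float:
    """Proportion of differing sites between two pre-aligned sequences.

    Columns where either symbol is not a plain A/C/G/T base (gaps, N) are
    excluded from numerator and denominator.  Symmetric, zero on identical
    input; errors on length mismatch or zero comparable columns.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError(
            f"aligned lengths differ: {len(seq_a)} vs {len(seq_b)}"
        )
    a = encode(seq_a)
    b = encode(seq_b)
    valid_a = (a == ord("A")) | (a == ord("C")) | (a == ord("G")) | (a == ord("T"))
    valid_b = (b == ord("A")) | (b == ord("C")) | (b == ord("G")) | (b == ord("T"))
    comparable = valid_a & valid_b
    n = int(comparable.sum())
    if n == 0:
        raise ValueError("no comparable (both A/C/G/T) columns")
    diff = int((comparable & (a != b)).sum())
    return diff / n


def _unique_kmer_positions(seq: str, k: int) -> dict[str, int]:
    counts: dict[str, int] = {}
    pos: dict[str, int] = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        counts[kmer] = counts.get(kmer, 0) + 1
        pos.setdefault(kmer, i)
    return {kmer: p for kmer, p in pos.items() if counts[kmer] == 1}


def _colinear_chain(pairs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Longest chain of anchor pairs strictly increasing in both coordinates
    (patience-style LIS on the second coordinate after sorting by the first)."""
    pairs = sorted(pairs)
    tails: list[int] = []  # tails[i] = smallest pb ending a chain of length i+1
    tail_idx: list[int] = []
    prev = [-1] * len(pairs)
    for idx, (_, pb) in enumerate(pairs):
        j = bisect.bisect_left(tails, pb)
        if j == len(tails):
            tails.append(pb)
            tail_idx.append(idx)
        else:
            tails[j] = pb
            tail_idx[j] = idx
        prev[idx] = tail_idx[j - 1] if j > 0 else -1
    chain: list[tuple[int, int]] = []
    cursor = tail_idx[-1] if tail_idx else -1
    while cursor != -1:
        chain.append(pairs[cursor])
        cursor = prev[cursor]
    return chain[::-1]


def _edlib_gapped(a: str, b: str, band: int | None) -> tuple[str, str]:
    if not a and not b:
        return "", ""
    if not a:
        return "-" * len(b), b
    if not b:
        return a, "-" * len(a)
    if a == b:
        return a, b
    res = edlib.align(a, b, mode="NW", task="path", k=band if band else -1)
    if res["editDistance"] < 0:
        raise AlignmentError(f"segment alignment exceeded band {band}")
    return cigar_to_gapped(a, b, res["cigar"])


def anchored_align(
    seq_a: str,
    seq_b: str,
    k: int = 15,
    band: int | None = None,
    anchor_stride: int = 200,
) -> tuple[str, str]:
    """Global alignment of two related sequences by unique-k-mer anchoring.

    k-mers occurring exactly once in each sequence are matched, chained
    colinearly, thinned to roughly one anchor per ``anchor_stride`` bases,
    and the inter-anchor segments (plus head and tail) are filled by global
    edit-distance alignment.  Output is a pair of equal-length strings with
    '-' gaps.  Raises AlignmentError when no colinear anchor chain exists —
    such pairs are too diverged for this aligner and should be aligned with
    a general-purpose multiple aligner instead.
    """
    if not seq_a or not seq_b:
        raise ValueError("anchored_align requires non-empty sequences")
    ua = _unique_kmer_positions(seq_a, k)
    ub = _unique_kmer_positions(seq_b, k)
    pairs = [(pa, ub[kmer]) for kmer, pa in ua.items() if kmer in ub]
    chain = _colinear_chain(pairs) if pairs else []
    if not chain:
        raise AlignmentError(
            "no colinear anchor chain between sequences; "
            "align externally and use p_distance on the result"
        )
    thinned = [chain[0]]
    for pa, pb in chain[1:]:
        if pa - thinned[-1][0] >= anchor_stride and pb - thinned[-1][1] >= anchor_stride:
            thinned.append((pa, pb))
    out_a: list[str] = []
    out_b: list[str] = []
    prev_a = prev_b = 0
    for pa, pb in thinned:
        ga, gb = _edlib_gapped(seq_a[prev_a:pa], seq_b[prev_b:pb], band)
        out_a.append(ga)
        out_b.append(gb)
        prev_a, prev_b = pa, pb
    ga, gb = _edlib_gapped(seq_a[prev_a:], seq_b[prev_b:], band)
    out_a.append(ga)
    out_b.append(gb)
    return "".join(out_a), "".join(out_b)


@dataclass
class DistanceReport:
    """Pairwise p-distances among assemblies plus intra/inter summaries.

    ``intra`` is the reference-vs-assembly distance per species (how far the
    sample's genome drifted from the public reference); ``inter`` is the
    mean distance from a species' assembly to every other species' assembly
    (None when the panel holds a single species).
    """

    pairwise: pd.DataFrame
    intra: dict[str, float]
    inter: dict[str, float | None]

    def to_frame(self) -> pd.DataFrame:
        species = sorted(self.intra)
        return pd.DataFrame(
            {
                "species_id": species,
                "intra_distance": [self.intra[s] for s in species],
                "inter_mean_distance": [self.inter[s] for s in species],
            }
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6f")


def _aligned_distance(a: str, b: str, label: str, **kwargs) -> float:
    try:
        ga, gb = anchored_align(a, b, **kwargs)
        return p_distance(ga, gb)
    except (AlignmentError, ValueError) as exc:
        raise AlignmentError(f"distance for pair {label} failed: {exc}") from exc


def distance_report(
    references: ReferenceDB,
    assemblies: dict[str, Mitogenome],
    **align_kwargs,
) -> DistanceReport:
    """Intra- vs inter-specific p-distances for a set of assembled genomes.

    For each species the intra distance compares its assembly to its
    reference; the inter distance averages the assembly's distance to every
    other assembly.  Each pair is aligned with :func:`anchored_align`.
    """
    unknown = sorted(set(assemblies) - set(references.genomes))
    if unknown:
        raise ValueError(f"assemblies for species not in the panel: {unknown}")
    species = sorted(assemblies)
    dist = pd.DataFrame(0.0, index=species, columns=species)
    for i, s in enumerate(species):
        for t in species[i + 1 :]:
            d = _aligned_distance(
                assemblies[s].sequence, assemblies[t].sequence, f"({s}, {t})", **align_kwargs
            )
            dist.loc[s, t] = dist.loc[t, s] = d
    intra = {
        s: _aligned_distance(
            references.genomes[s].sequence,
            assemblies[s].sequence,
            f"(ref {s}, asm {s})",
            **align_kwargs,
        )
        for s in species
    }
    inter: dict[str, float | None] = {}
    for s in species:
        others = [dist.loc[s, t] for t in species if t != s]
        inter[s] = float(np.mean(others)) if others else None
    return DistanceReport(pairwise=dist, intra=intra, inter=inter)
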