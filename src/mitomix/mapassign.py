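"""Steps S3-S4: map mitochondrial reads to every assembly, keep unique hits.

Mitogenomes of related species are conserved enough that a read often maps
to several of them; counting those multi-mappers would overstate every
species.  So each species' assembled genome is screened independently (S3)
and a read only counts for a species when it mapped to that species and no
other (S4).  Uniquely mapped reads are the quantification currency of the
whole method.

The mapper acceptance rule is deterministic and tool-independent: a read
belongs to a species' mapped set iff its best banded end-to-end alignment
(either orientation) against that species' assembly has edit distance at
most floor(max_edit_frac * read_length).  Set semantics on read ids mean a
read aligning at two loci of one genome counts once.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import edlib
import pandas as pd

from ._align import revcomp
from .consensus import ConsensusGenome
from .seqio import ReadRecord

__all__ = [
    "MappedSets",
    "UniqueAssignment",
    "MultimapSummary",
    "map_reads",
    "assign_unique",
    "multimap_summary",
    "multimap_table",
]


@dataclass
class MappedSets:
    """Per-species sets of accepted read ids (sets may overlap)."""

    sets: dict[str, set[str]]
    read_ids: list[str]

    @property
    def total_mito_reads(self) -> int:
        return len(self.read_ids)


@dataclass
class UniqueAssignment:
    """Partition of mapped reads into unique / ambiguous / unassigned.

    Unique sets are pairwise disjoint and together with ``ambiguous`` and
    ``unassigned`` they tile the extracted mitochondrial reads exactly.
    """

    unique: dict[str, set[str]]
    ambiguous: set[str]
    unassigned: set[str]

    def counts(self) -> dict[str, int]:
        return {s: len(ids) for s, ids in self.unique.items()}


@dataclass
class MultimapSummary:
    """Per-species unique fractions plus the global mean non-specific share."""

    table: pd.DataFrame
    mean_nonspecific_pct: float | None


def map_reads(
    mito_reads: Iterable[ReadRecord],
    assemblies: Mapping[str, ConsensusGenome],
    max_edit_frac: float = 0.1,
) -> MappedSets:
    """Screen every read against every assembled genome independently."""
    if not assemblies:
        raise ValueError("map_reads requires at least one assembly")
    reads = list(mito_reads)
    oriented = [(r.read_id, r.sequence, revcomp(r.sequence)) for r in reads]
    sets: dict[str, set[str]] = {}
    for species in sorted(assemblies):
        genome = assemblies[species].genome
        target = genome.sequence * 2 if genome.circular else genome.sequence
        accepted: set[str] = set()
        for read_id, fwd, rev in oriented:
            k = math.floor(max_edit_frac * len(fwd))
            if edlib.align(fwd, target, mode="HW", task="distance", k=k)["editDistance"] >= 0:
                accepted.add(read_id)
            elif edlib.align(rev, target, mode="HW", task="distance", k=k)["editDistance"] >= 0:
                accepted.add(read_id)
        sets[species] = accepted
    return MappedSets(sets=sets, read_ids=[r.read_id for r in reads])


def assign_unique(mapped: MappedSets) -> UniqueAssignment:
    """Partition read ids by how many species' mapped sets contain them."""
    membership: dict[str, int] = {}
    for ids in mapped.sets.values():
        for read_id in ids:
            membership[read_id] = membership.get(read_id, 0) + 1
    unique = {
        species: {rid for rid in ids if membership[rid] == 1}
        for species, ids in mapped.sets.items()
    }
    ambiguous = {rid for rid, n in membership.items() if n >= 2}
    unassigned = {rid for rid in mapped.read_ids if rid not in membership}
    return UniqueAssignment(unique=unique, ambiguous=ambiguous, unassigned=unassigned)


def multimap_table(
    total_mapped: Mapping[str, int], unique_mapped: Mapping[str, int]
) -> MultimapSummary:
    """Unique/non-specific percentages from per-species count mappings.

    Species with zero mapped reads get NaN percentages and are excluded
    from the global mean non-specific fraction (None when no species
    mapped anything).
    """
    species = sorted(total_mapped)
    rows = []
    for s in species:
        total = int(total_mapped[s])
        uniq = int(unique_mapped.get(s, 0))
        pct = 100.0 * uniq / total if total else float("nan")
        rows.append((s, total, uniq, pct, 100.0 - pct if total else float("nan")))
    table = pd.DataFrame(
        rows,
        columns=["species_id", "total_mapped", "unique_mapped", "unique_pct", "nonspecific_pct"],
    ).set_index("species_id")
    valid = table["nonspecific_pct"].dropna()
    mean_ns = float(valid.mean()) if len(valid) else None
    return MultimapSummary(table=table, mean_nonspecific_pct=mean_ns)


def multimap_summary(mapped: MappedSets, unique: UniqueAssignment) -> MultimapSummary:
    """Per-species unique fraction and global mean non-specific fraction."""
    return multimap_table(
        {s: len(ids) for s, ids in mapped.sets.items()},
        {s: len(ids) for s, ids in unique.unique.items()},
    )
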