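"""Synthetic data: mitogenome panels, error-bearing reads, mixtures, spike series.

The generator emulates the study conditions the pipeline is evaluated
under: a panel of diverged mitogenomes (a star phylogeny around a random
ancestor), single-end Illumina-like reads with substitution errors and
constant Q30 qualities, and labelled two-species spike-in series (a minor
"contaminant" species mixed into a major background at a grid of
percentages, five replicates per level, 30,000 reads per dataset by
default).  Every read carries its source species as a truth label so every
pipeline stage can be scored offline.

All generators are bit-reproducible given their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .refdb import Mitogenome
from .seqio import ReadRecord
from ._align import revcomp

__all__ = [
    "SimConfig",
    "SpikeDesign",
    "SpikeDataset",
    "simulate_panel",
    "simulate_reads",
    "build_mixture",
    "build_spike_series",
    "add_offtarget_reads",
    "divergence_to_mutation",
    "write_truth_table",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: Spike levels (percent minor species) used in the reference experiment.
DEFAULT_SPIKE_LEVELS = (
    0.01, 0.1, 1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 20, 30, 40, 50, 60, 70, 80, 90, 100,
)


def _round_half_up(x: float) -> int:
    """round() half away from zero for non-negative x (0.01% of 30000 -> 3)."""
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class SimConfig:
    """Read-simulation settings.

    read_length : bases per single-end read (HiSeq-class default 150)
    error_rate  : per-base substitution probability (default 0.002, the
                  right order for post-QC Illumina data)
    """

    read_length: int = 150
    error_rate: float = 0.002
    seed: int = 0
    circular: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.error_rate < 0.5:
            raise ValueError(f"error_rate {self.error_rate} outside [0, 0.5)")
        if self.read_length < 1:
            raise ValueError("read_length must be positive")


@dataclass(frozen=True)
class SpikeDesign:
    """A two-species spike-in series: minor percentages of a fixed total.

    Defaults reproduce the reference design: 30,000 reads per dataset,
    levels 0.01-100%, five replicates.
    """

    major_species: str
    minor_species: str
    total_reads: int = 30_000
    levels: tuple[float, ...] = DEFAULT_SPIKE_LEVELS
    replicates: int = 5

    def __post_init__(self) -> None:
        if self.total_reads < 1 or self.replicates < 1:
            raise ValueError("total_reads and replicates must be positive")
        for lv in self.levels:
            if not 0.0 < lv <= 100.0:
                raise ValueError(f"spike level {lv} outside (0, 100]")

    def minor_count(self, level: float) -> int:
        return _round_half_up(self.total_reads * level / 100.0)


@dataclass(frozen=True)
class SpikeDataset:
    """One labelled spike dataset: reads plus its design coordinates."""

    sample_id: str
    level: float
    replicate: int
    minor_count: int
    major_count: int
    reads: tuple[ReadRecord, ...]


def simulate_panel(
    n_species: int,
    length: int,
    mutation_fraction: float,
    seed: int,
    species_ids: list[str] | None = None,
    circular: bool = True,
) -> list[Mitogenome]:
    """Star-phylogeny panel: one random ancestor, each species an independent
    mutant of it.

    Each species genome carries exactly ``round(mutation_fraction * length)``
    substituted sites, chosen without replacement, each replaced by a
    uniform choice among the three other bases.  The expected pairwise
    p-distance between two species is ``2m(1-m) + (2/3)m**2``.
    """
    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    if not 0.0 <= mutation_fraction < 0.3:
        raise ValueError(f"mutation_fraction {mutation_fraction} outside [0, 0.3)")
    if species_ids is None:
        species_ids = [f"sp{i + 1:02d}" for i in range(n_species)]
    elif len(species_ids) != n_species:
        raise ValueError("species_ids length must equal n_species")
    rng = np.random.default_rng(seed)
    ancestor = rng.choice(_BASES, size=length)
    n_sub = _round_half_up(mutation_fraction * length)
    genomes = []
    for sid in species_ids:
        seq = ancestor.copy()
        if n_sub:
            sites = rng.choice(length, size=n_sub, replace=False)
            # shift by 1..3 positions in base order = uniform over other bases
            current = np.searchsorted(_BASES, seq[sites])
            shifted = (current + rng.integers(1, 4, size=n_sub)) % 4
            seq[sites] = _BASES[shifted]
        genomes.append(
            Mitogenome(sid, seq.tobytes().decode("ascii"), circular=circular)
        )
    return genomes


def _apply_errors(seq: np.ndarray, error_rate: float, rng: np.random.Generator) -> np.ndarray:
    if error_rate <= 0.0:
        return seq
    hit = rng.random(seq.size) < error_rate
    n = int(hit.sum())
    if n:
        current = np.searchsorted(_BASES, seq[hit])
        seq = seq.copy()
        seq[hit] = _BASES[(current + rng.integers(1, 4, size=n)) % 4]
    return seq


def simulate_reads(
    genome: Mitogenome,
    n: int,
    config: SimConfig,
    id_prefix: str | None = None,
) -> list[ReadRecord]:
    """Draw n single-end reads uniformly from a genome.

    Start positions are uniform on the circle (reads may span the origin);
    strand is Bernoulli(1/2) with the reverse complement emitted; each base
    is substituted with probability ``error_rate``; qualities are constant
    Q30 and ``truth_species`` is set to the genome's species label.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    L = len(genome)
    rl = config.read_length
    if rl > L:
        raise ValueError(f"read_length {rl} exceeds genome length {L}")
    prefix = id_prefix if id_prefix is not None else genome.species_id
    rng = np.random.default_rng(config.seed)
    circular = config.circular and genome.circular
    extended = np.frombuffer(
        (genome.sequence * 2 if circular else genome.sequence).encode("ascii"),
        dtype=np.uint8,
    )
    max_start = L if circular else L - rl + 1
    starts = rng.integers(0, max_start, size=n)
    strands = rng.random(n) < 0.5
    quals = (30,) * rl
    reads = []
    for i in range(n):
        frag = _apply_errors(extended[starts[i] : starts[i] + rl], config.error_rate, rng)
        seq = frag.tobytes().decode("ascii")
        if strands[i]:
            seq = revcomp(seq)
        reads.append(
            ReadRecord(
                read_id=f"{prefix}_{i:07d}",
                sequence=seq,
                qualities=quals,
                truth_species=genome.species_id,
            )
        )
    return reads


def build_mixture(
    readsets: dict[str, list[ReadRecord]],
    counts: dict[str, int],
    seed: int,
) -> list[ReadRecord]:
    """Sample reads per species without replacement, pool, and shuffle.

    Truth labels travel with the reads, so label counts in the output equal
    the requested design exactly.  Asking for more reads than a pool holds
    is an error naming the species.
    """
    rng = np.random.default_rng(seed)
    pooled: list[ReadRecord] = []
    for species in sorted(counts):
        want = counts[species]
        have = readsets.get(species, [])
        if want > len(have):
            raise ValueError(
                f"species {species!r}: requested {want} reads, pool has {len(have)}"
            )
        if want:
            idx = rng.choice(len(have), size=want, replace=False)
            pooled.extend(have[j] for j in idx)
    order = rng.permutation(len(pooled))
    return [pooled[j] for j in order]


def build_spike_series(
    design: SpikeDesign,
    major_reads: list[ReadRecord],
    minor_reads: list[ReadRecord],
    seed: int,
) -> list[SpikeDataset]:
    """Materialise every (level, replicate) dataset of a spike design.

    The minor-species count at each level is round(total * level / 100);
    the major species fills the remainder.  Replicate r draws with seed
    ``seed + r`` so the five replicates are distinct but reproducible.
    """
    datasets = []
    for li, level in enumerate(design.levels):
        minor_n = design.minor_count(level)
        major_n = design.total_reads - minor_n
        for r in range(design.replicates):
            reads = build_mixture(
                {design.major_species: major_reads, design.minor_species: minor_reads},
                {design.major_species: major_n, design.minor_species: minor_n},
                seed=seed + r,
            )
            datasets.append(
                SpikeDataset(
                    sample_id=f"SD{li + 1:02d}-R{r + 1}",
                    level=level,
                    replicate=r + 1,
                    minor_count=minor_n,
                    major_count=major_n,
                    reads=tuple(reads),
                )
            )
    return datasets


def add_offtarget_reads(
    reads: list[ReadRecord],
    n_noise: int,
    length: int,
    seed: int,
) -> list[ReadRecord]:
    """Append uniform-random background reads labelled "offtarget".

    Emulates the non-mitochondrial bulk of a shotgun library (in real meat
    samples >99% of reads); random sequences essentially never share a
    21-mer with a 16 kb panel (collision probability ~ L*n*4^-21).
    """
    rng = np.random.default_rng(seed)
    quals = (30,) * length
    noise = [
        ReadRecord(
            read_id=f"offtarget_{i:07d}",
            sequence=rng.choice(_BASES, size=length).tobytes().decode("ascii"),
            qualities=quals,
            truth_species="offtarget",
        )
        for i in range(n_noise)
    ]
    return list(reads) + noise


def divergence_to_mutation(p: float) -> float:
    """Per-species mutation fraction m giving expected pairwise p-distance p.

    Inverts p = 2m(1-m) + (2/3)m^2 for a star phylogeny with independent
    uniform substitutions.
    """
    if not 0.0 <= p < 0.74:
        raise ValueError("target divergence must be in [0, 0.74)")
    # (4/3) m^2 - 2 m + p = 0, smaller root
    return (2.0 - math.sqrt(4.0 - (16.0 / 3.0) * p)) / (8.0 / 3.0)


def write_truth_table(path, reads: list[ReadRecord]) -> None:
    """Write (read_id, truth_species) provenance as a TSV."""
    with open(path, "wt") as handle:
        handle.write("read_id\ttruth_species\n")
        for read in reads:
            handle.write(f"{read.read_id}\t{read.truth_species or ''}\n")
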