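"""Composition reporting: proportions, presence calls, correction factors.

Presence of a species is called when its uniquely mapped reads exceed a
threshold fraction (default 2%, strictly greater-than) of all mitochondrial
reads in the sample.  Because species differ in mitochondrial DNA content
per gram of muscle, equal meat masses do not yield equal read counts;
species-specific correction factors — the mean over equal-mass replicates
of the ratio of a species' unique count to a baseline species' unique
count — convert unique-read counts into relative biomass.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .mapassign import MappedSets, UniqueAssignment

__all__ = [
    "CompositionReport",
    "CorrectionFactors",
    "MassFractions",
    "composition_report",
    "aggregate_presence",
    "correction_factors",
    "corrected_mass_fractions",
]


@dataclass
class CompositionReport:
    """Per-species composition table for one sample.

    Columns: total_mapped (NaN when mapped sets were not supplied),
    unique_mapped, unique_pct_of_mapped, unique_pct_of_mito, present.
    Percentages are kept at full precision; rounding to two decimals
    happens only in the TSV writer.
    """

    table: pd.DataFrame
    total_mito_reads: int
    threshold: float

    @property
    def present_species(self) -> list[str]:
        return sorted(self.table.index[self.table["present"]])

    def write_tsv(self, path) -> None:
        out = self.table.copy()
        for col in ("unique_pct_of_mapped", "unique_pct_of_mito"):
            out[col] = out[col].round(2)
        out.to_csv(path, sep="\t")


@dataclass
class CorrectionFactors:
    """Relative read-count-to-biomass factors against a baseline species.

    factor[s] = mean over replicates of unique[s] / unique[baseline]; the
    baseline's factor is exactly 1.
    """

    baseline_species: str
    factors: pd.Series
    n_replicates: int

    def rounded(self, decimals: int = 2) -> pd.Series:
        return self.factors.round(decimals)

    def write_tsv(self, path) -> None:
        out = pd.DataFrame(
            {
                "species_id": self.factors.index,
                "factor": self.factors.round(2).values,
                "n_replicates": self.n_replicates,
            }
        )
        out.to_csv(path, sep="\t", index=False)


@dataclass
class MassFractions:
    """Corrected relative biomass estimates; ``excluded`` lists species
    dropped for lack of a correction factor."""

    fractions: pd.Series
    excluded: list[str]


def _unique_counts(unique: UniqueAssignment | Mapping[str, int]) -> dict[str, int]:
    if isinstance(unique, UniqueAssignment):
        return unique.counts()
    return {s: int(c) for s, c in unique.items()}


def composition_report(
    unique: UniqueAssignment | Mapping[str, int],
    total_mito: int,
    threshold: float = 0.02,
    mapped: MappedSets | Mapping[str, int] | None = None,
) -> CompositionReport:
    """Build the per-species composition table for one sample.

    ``unique`` may be a UniqueAssignment or a plain species -> count
    mapping (so printed count tables can be re-analysed without sequence
    data).  Presence requires unique/total_mito strictly above the
    threshold.
    """
    if total_mito <= 0:
        raise ValueError("total_mito must be positive")
    counts = _unique_counts(unique)
    if sum(counts.values()) > total_mito:
        raise ValueError("sum of unique counts exceeds total mitochondrial reads")
    if isinstance(mapped, MappedSets):
        mapped_counts: Mapping[str, int] | None = {
            s: len(ids) for s, ids in mapped.sets.items()
        }
    else:
        mapped_counts = mapped
    species = sorted(counts)
    rows = []
    for s in species:
        uniq = counts[s]
        total = mapped_counts.get(s) if mapped_counts is not None else None
        pct_mapped = 100.0 * uniq / total if total else float("nan")
        pct_mito = 100.0 * uniq / total_mito
        rows.append((s, total, uniq, pct_mapped, pct_mito, pct_mito / 100.0 > threshold))
    table = pd.DataFrame(
        rows,
        columns=[
            "species_id",
            "total_mapped",
            "unique_mapped",
            "unique_pct_of_mapped",
            "unique_pct_of_mito",
            "present",
        ],
    ).set_index("species_id")
    return CompositionReport(table=table, total_mito_reads=total_mito, threshold=threshold)


def aggregate_presence(reports: Sequence[CompositionReport]) -> pd.Series:
    """Species is present overall iff present in at least one replicate."""
    if not reports:
        raise ValueError("no reports to aggregate")
    species = sorted({s for r in reports for s in r.table.index})
    out = pd.Series(False, index=pd.Index(species, name="species_id"), name="present")
    for r in reports:
        for s in r.table.index[r.table["present"]]:
            out[s] = True
    return out


def correction_factors(
    unique_counts: pd.DataFrame, baseline: str
) -> CorrectionFactors:
    """Mean-of-ratios correction factors from an equal-mass replicate matrix.

    ``unique_counts`` is species x replicate.  The factor is the mean over
    replicates of the per-replicate ratio to the baseline (not the ratio of
    sums — the two differ whenever replicates vary in depth).  Every
    baseline replicate must have a positive count.
    """
    if baseline not in unique_counts.index:
        raise ValueError(f"baseline species {baseline!r} not in counts")
    base = unique_counts.loc[baseline].astype(float)
    if (base <= 0).any():
        bad = list(unique_counts.columns[base <= 0])
        raise ValueError(f"baseline {baseline!r} has non-positive counts in replicates {bad}")
    ratios = unique_counts.astype(float).div(base, axis=1)
    factors = ratios.mean(axis=1)
    factors.loc[baseline] = 1.0
    factors.name = "factor"
    return CorrectionFactors(
        baseline_species=baseline,
        factors=factors,
        n_replicates=unique_counts.shape[1],
    )


def corrected_mass_fractions(
    unique_counts: Mapping[str, int] | pd.Series,
    factors: CorrectionFactors,
) -> MassFractions:
    """Relative biomass per species: mass[s] proportional to count/factor.

    Species without a factor are excluded from the normalisation and
    reported in ``excluded``.  Included fractions sum to one.
    """
    counts = pd.Series(dict(unique_counts), dtype=float)
    excluded = sorted(set(counts.index) - set(factors.factors.index))
    included = counts.drop(excluded)
    weights = included / factors.factors.loc[included.index]
    total = weights.sum()
    if total <= 0:
        raise ValueError("no positive corrected counts to normalise")
    fractions = weights / total
    fractions.name = "mass_fraction"
    return MassFractions(fractions=fractions.sort_index(), excluded=excluded)
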