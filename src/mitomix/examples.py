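"""Bundled worked-example count tables from a published 15-species study.

Three small TSVs ship with the package so the counting arithmetic —
unique-read percentages, correction factors, spike-in error statistics —
can be exercised and checked without any sequence data:

* ``meatmix15_unique_counts`` — mapped and uniquely mapped read counts per
  species for an equal-mass mixture of meat from 15 mammalian and avian
  species, sequenced in triplicate (replicates R1-R3).
* ``meatmix15_read_totals`` — clean-read and mitochondrial-read totals for
  the same three libraries.
* ``spike_detected_counts`` — detected minor-species (chicken) unique-read
  counts for a 21-level pork/chicken spike-in simulation, five replicates
  per level.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "meatmix15_unique_counts",
    "meatmix15_read_totals",
    "spike_detected_counts",
    "meatmix15_unique_matrix",
    "PIG",
]

#: Baseline species for correction factors in the equal-mass example.
PIG = "Sus_scrofa_domesticus"


def _load(name: str) -> pd.DataFrame:
    with resources.files("mitomix.data").joinpath(name).open("r") as handle:
        return pd.read_csv(handle, sep="\t")


def meatmix15_unique_counts() -> pd.DataFrame:
    """Long-format per-(species, replicate) mapped/unique read counts."""
    return _load("meatmix15_unique_counts.tsv")


def meatmix15_read_totals() -> pd.DataFrame:
    """Clean-read and mitochondrial-read totals per replicate library."""
    return _load("meatmix15_read_totals.tsv")


def spike_detected_counts() -> pd.DataFrame:
    """Spike-series detected counts: one row per level, columns r1..r5."""
    return _load("spike_detected_counts.tsv")


def meatmix15_unique_matrix() -> pd.DataFrame:
    """Unique counts pivoted to species x replicate (correction-factor input)."""
    return meatmix15_unique_counts().pivot(
        index="species_id", columns="replicate", values="unique_mapped"
    )
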