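from __future__ import annotations

import numpy as np
import pytest

from mitomix.refdb import Mitogenome, build_db
from mitomix.simdata import SimConfig, divergence_to_mutation, simulate_panel, simulate_reads

PANEL_SEED = 101
PANEL_LENGTH = 2000
PANEL_DIVERGENCE = 0.2


def mutate_sites(sequence: str, n_sites: int, seed: int) -> str:
    """Independent truth-maker: substitute exactly n_sites positions."""
    rng = np.random.default_rng(seed)
    bases = "ACGT"
    seq = list(sequence)
    sites = rng.choice(len(seq), size=n_sites, replace=False)
    for pos in sites:
        alternatives = [b for b in bases if b != seq[pos]]
        seq[pos] = alternatives[rng.integers(0, 3)]
    return "".join(seq)


@pytest.fixture(scope="session")
def panel3() -> list[Mitogenome]:
    """Three 2 kb mitogenomes at ~20% pairwise divergence."""
    return simulate_panel(
        3,
        PANEL_LENGTH,
        divergence_to_mutation(PANEL_DIVERGENCE),
        seed=PANEL_SEED,
        species_ids=["alpha", "beta", "gamma"],
    )


@pytest.fixture(scope="session")
def db3(panel3):
    return build_db(panel3, k=21)


@pytest.fixture(scope="session")
def reads_by_species(panel3):
    """500 labelled reads per panel species at the default error rate."""
    return {
        g.species_id: simulate_reads(g, 500, SimConfig(seed=PANEL_SEED + i))
        for i, g in enumerate(panel3)
    }
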