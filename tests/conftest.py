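"""Shared fixtures: small deterministic taxonomies and communities."""

from __future__ import annotations

import numpy as np
import pytest

from taxoclass import (
    SimulationConfig,
    TaxonomyShape,
    build_taxonomy,
    evolve_genomes,
    synth_taxonomy,
)
from taxoclass.simulate import DEFAULT_DIVERGENCE

CHAIN_RECORDS = [
    (1, 1, "root", "root"),
    (2, 1, "phylum", "P"),
    (3, 2, "class", "C"),
    (4, 3, "order", "O"),
    (5, 4, "family", "F"),
    (6, 5, "genus", "G"),
    (7, 6, "species", "S"),
]


@pytest.fixture(scope="session")
def chain_tax():
    """Minimal 7-node root-to-species chain."""
    return build_taxonomy(CHAIN_RECORDS)


@pytest.fixture(scope="session")
def toy_tax():
    """2 phyla x 2 genera x 3 species = 12 species, 25 nodes."""
    return synth_taxonomy(TaxonomyShape(2, 1, 1, 1, 2, 3))


@pytest.fixture(scope="session")
def small_community():
    """Evolved two-genus community (6 species) at default divergences."""
    cfg = SimulationConfig(shape=TaxonomyShape(1, 1, 1, 1, 2, 3),
                           genome_len=15_000, reads_per_species=100)
    t = synth_taxonomy(cfg.shape)
    return evolve_genomes(t, cfg), cfg


def confusable_config(seed: int, **overrides) -> SimulationConfig:
    """Two genera of three sister species at 0.5% species divergence —
    the regime where species-level k-mer evidence becomes scarce."""
    div = dict(DEFAULT_DIVERGENCE)
    div["species"] = 0.005
    kwargs = dict(
        shape=TaxonomyShape(1, 1, 1, 1, 2, 3),
        divergence=div,
        genome_len=20_000,
        seed=seed,
    )
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)


def random_sequence(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))
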