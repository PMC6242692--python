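"""Shared fixtures: deterministic toy genomes and a default simulated screen."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from crispriscreen.genome import Genome
from crispriscreen.simulate import SimulationConfig, simulate_screen_suite


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


@pytest.fixture(scope="session")
def default_suite():
    """Full default simulation (200 genes, 8,000 guides, 3 replicates,
    depth 1e6) shared across recovery tests."""
    return simulate_screen_suite(SimulationConfig(seed=1))


@pytest.fixture
def toy_genes() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "name": ["gA", "gB", "gC"],
            "left": [100, 400, 700],
            "right": [300, 600, 950],
            "strand": ["+", "-", "+"],
            "essential": [True, False, False],
            "tu_id": ["tu1", "tu1", "tu2"],
            "tu_rank": [1, 2, 1],
        }
    )


@pytest.fixture
def toy_genome() -> Genome:
    rng = np.random.default_rng(42)
    return Genome("toy", random_sequence(rng, 1200), circular=True)
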