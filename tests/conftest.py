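import numpy as np
import pandas as pd
import pytest

from esnp.simulate import (
    LocusSpec,
    PlantedEffect,
    SimulationSpec,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def small_spec() -> SimulationSpec:
    """A reduced dataset (2 loci, 40 probes) for fast structural tests."""
    loci = [
        LocusSpec("SNCA", "4", 6, 90_600_000, 15_000, (0.2, 0.45), 0.8),
        LocusSpec("MAPT", "17", 5, 43_900_000, 12_000, (0.2, 0.45), 0.9),
    ]
    effects = [
        PlantedEffect("SNCA_snp002", "cis_SNCA_probe1", 1.0, 1.0, "shared"),
        PlantedEffect("MAPT_snp003", "bg_probe0005", 0.9, 0.0, "case_only"),
    ]
    return SimulationSpec(
        loci=loci, n_probes=40, probes_per_locus=4, effects=effects, seed=11
    )


@pytest.fixture(scope="session")
def small_dataset(small_spec):
    return simulate_dataset(small_spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
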