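"""Shared fixtures: small simulated datasets and the desk-scale ABC
reference table (built once per session, only when a test asks for it)."""

from __future__ import annotations

import numpy as np
import pytest

import invadepop as ip


@pytest.fixture(scope="session")
def bottleneck_dataset():
    """A two-era dataset under a founder-bottleneck demography."""
    dem = ip.Demography(((0, 75), (50, 5000)), "bottleneck")
    return ip.simulate_snp_dataset(dem, ip.two_era_scheme(8, 60), 250, seed=7)


@pytest.fixture(scope="session")
def river_dataset():
    """A stepping-stone river population with isolation by distance."""
    return ip.simulate_river_population(
        15, 60, 0.05, 60, 200, 6, deme_spacing_km=20.0, seed=11
    )


@pytest.fixture(scope="session")
def desk_reference_table():
    """Desk-scale ABC training set: 500 rows/scenario at 300 loci on the
    8 + 195 two-era design (the study's observed dimensions)."""
    return ip.build_reference_table(
        n_per_scenario=500, n_loci=300, n_historical=8, n_contemporary=195, seed=202,
    )


def hwe_matrix(n: int, n_loci: int, seed: int, p_range=(0.1, 0.9)) -> ip.GenotypeMatrix:
    """Genotypes in exact Hardy-Weinberg proportions (binomial draws)."""
    rng = np.random.default_rng(seed)
    p = rng.uniform(*p_range, n_loci)
    codes = rng.binomial(2, p, size=(n, n_loci)).astype(np.int16)
    return ip.GenotypeMatrix(
        codes, [f"i{k}" for k in range(n)], [f"l{j}:1" for j in range(n_loci)]
    )
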