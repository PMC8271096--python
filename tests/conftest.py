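"""Shared fixtures: small synthetic cohorts and networks built at test time."""

import numpy as np
import pytest

import parcelfit as pf


@pytest.fixture(scope="session")
def small_hierarchy():
    """48 fine units clustered into nested levels of 48, 24 and 12 regions."""
    return pf.make_parcellation_hierarchy(48, [48, 24, 12], seed=7)


@pytest.fixture(scope="session")
def small_connectome(small_hierarchy):
    return pf.make_structural_connectome(small_hierarchy[1], seed=7)


@pytest.fixture(scope="session")
def small_network(small_connectome):
    return pf.build_network(small_connectome)


@pytest.fixture(scope="session")
def tiny_cohort():
    """Three 12-region subjects with phase-model ground truth (tau=6, C=0.3)."""
    levels = pf.make_parcellation_hierarchy(12, [12, 6], seed=3)
    bundles = pf.make_bold_cohort(
        3, levels[0], {"model_kind": "phase", "tau": 6.0, "coupling": 0.3},
        seed=3)
    return levels, bundles


@pytest.fixture(scope="session")
def regional_params():
    rng = np.random.default_rng(5)
    return pf.RegionalParameters(frequencies=rng.uniform(0.02, 0.09, 24),
                                 amplitudes=rng.normal(0.5, 0.4, 24))
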