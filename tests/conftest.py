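"""Shared fixtures: small synthetic worlds generated once per session."""

import numpy as np
import pytest

from memfam.synthetic import GeneratorConfig, generate_superfamily


@pytest.fixture(scope="session")
def small_truth():
    """A compact planted superfamily (4 families x 4 members) plus decoy."""
    return generate_superfamily(
        GeneratorConfig(
            seed=11,
            members_per_family=4,
            within_family_divergence=0.25,
            between_family_divergence=0.45,
        )
    )


@pytest.fixture(scope="session")
def zero_div_truth():
    """A single family of identical members from an exact tandem duplication."""
    return generate_superfamily(
        GeneratorConfig(
            seed=23,
            n_families=1,
            members_per_family=2,
            within_family_divergence=0.0,
            between_family_divergence=0.0,
            half_divergence=0.0,
            loop_del_prob=0.0,
            include_decoy=False,
        )
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
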