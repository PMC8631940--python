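"""Shared fixtures: a small synthetic analysis bundle and its components."""

import numpy as np
import pytest

from mgpmap.genotypes import assemble_genotype_block
from mgpmap.simulate import SimConfig, make_fixture, simulate_study

SMALL_CONFIG = dict(
    n_specimens=120,
    n_chromosomes=4,
    markers_per_chromosome=25,
    n_genes=40,
    causal_genes=("gene001", "gene002"),
    causal_term_size=8,
    n_landmarks=12,
    seed=42,
)


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(**SMALL_CONFIG)


@pytest.fixture(scope="session")
def small_study(small_config):
    return simulate_study(small_config)


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory, small_config):
    out = tmp_path_factory.mktemp("bundle")
    return make_fixture(small_config, out)


@pytest.fixture(scope="session")
def small_block(small_study):
    return assemble_genotype_block(small_study.gene_set, small_study.probs,
                                   small_study.marker_map)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
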