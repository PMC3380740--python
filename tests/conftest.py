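import numpy as np
import pytest

from hotspot_transreg.go_semantic import GoDag
from hotspot_transreg.synthetic_data import (
    MotifSpec,
    SyntheticConfig,
    generate_go_world,
    generate_world,
)


@pytest.fixture(scope="session")
def toy_dag() -> GoDag:
    """Root R with two is_a children A and B (single namespace)."""
    terms = {
        "R": ("root", "biological_process"),
        "A": ("term a", "biological_process"),
        "B": ("term b", "biological_process"),
    }
    edges = [("A", "R", "is_a"), ("B", "R", "is_a")]
    return GoDag.from_edges(terms, edges)


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    return SyntheticConfig(
        n_chromosomes=2,
        chromosome_length=600_000,
        n_hotspots=60,
        hotspot_length=600,
        min_distance=2_000,
        motifs=(
            MotifSpec("STRONG", "ACGTAGCCGTAT", 0.9, 0.1),
            MotifSpec("NULL", "CATGCGATACCA", 0.2, 0.2),
        ),
        seed=42,
    )


@pytest.fixture(scope="session")
def small_world(small_config):
    return generate_world(small_config)


@pytest.fixture(scope="session")
def small_go_world(small_config):
    return generate_go_world(small_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260920)
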