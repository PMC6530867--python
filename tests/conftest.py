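import numpy as np
import pandas as pd
import pytest

import psdnet as ps


@pytest.fixture
def toy_annotations() -> pd.DataFrame:
    """Three proteins, three domains: rows (1,1,0), (1,0,0), (1,0,1)."""
    return pd.DataFrame(
        [("P1", "d1"), ("P1", "d2"), ("P2", "d1"), ("P3", "d1"), ("P3", "d3")],
        columns=["protein_id", "domain_id"],
    )


@pytest.fixture
def toy_matrix(toy_annotations) -> pd.DataFrame:
    return ps.build_profile_matrix(toy_annotations)


@pytest.fixture(scope="session")
def default_universe() -> ps.SyntheticUniverse:
    return ps.generate_universe()


@pytest.fixture(scope="session")
def default_result(default_universe) -> ps.PipelineResult:
    return ps.run_pipeline(
        default_universe.annotations,
        default_universe.pathways,
        default_universe.gold_domain_pathway,
    )


@pytest.fixture(scope="session")
def tiny_universe() -> ps.SyntheticUniverse:
    """The <= 10-protein instance used for brute-force oracle checks."""
    return ps.generate_worked_example()


def random_profile_pairs(rng: np.random.Generator, n_cases: int, n_domains: int):
    """Yield (x, y, weights) triples with nondegenerate positive weights."""
    for _ in range(n_cases):
        x = rng.integers(0, 2, n_domains)
        y = rng.integers(0, 2, n_domains)
        w = rng.uniform(0.1, 10.0, n_domains)
        yield x, y, w
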