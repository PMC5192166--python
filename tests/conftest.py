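import numpy as np
import pandas as pd
import pytest

from elevgrad import SiteTable, TaxonCommunity, generate_sites


@pytest.fixture(scope="session")
def sites30() -> SiteTable:
    """Default 30-site synthetic gradient (871-4550 m)."""
    return generate_sites(seed=1)


@pytest.fixture
def simple_sites() -> SiteTable:
    """Five evenly spaced sites with minimal covariates."""
    return SiteTable(
        pd.DataFrame(
            {
                "site_id": ["a", "b", "c", "d", "e"],
                "elevation_m": [1000.0, 1500.0, 2000.0, 2500.0, 3000.0],
                "habitat": ["low", "low", "mid", "mid", "high"],
            }
        )
    )


def make_community(counts, site_ids=None, name="tax", kingdom="animal", is_census=False):
    counts = np.asarray(counts)
    if site_ids is None:
        site_ids = [f"s{i}" for i in range(counts.shape[0])]
    matrix = pd.DataFrame(
        counts, index=site_ids,
        columns=[f"{name}_sp{j}" for j in range(counts.shape[1])],
    )
    return TaxonCommunity(name, kingdom, matrix, is_census)


@pytest.fixture
def tiny_community():
    return make_community([[0, 2, 1], [0, 0, 0], [1, 1, 5]])
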