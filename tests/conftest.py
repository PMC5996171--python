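import numpy as np
import pandas as pd
import pytest

from rhizonet.feature_table import FeatureTable
from rhizonet.synthetic_data import FIXTURE_SEED, GeneratorConfig, generate_community


def make_metadata(samples, niches, habitat="managed"):
    return pd.DataFrame(
        {
            "niche": niches,
            "habitat": [habitat] * len(samples),
            "yield": ["high"] * len(samples),
            "marker": ["16S"] * len(samples),
        },
        index=pd.Index(samples, name="sample"),
    )


@pytest.fixture
def toy_table():
    """3 taxa x 4 samples with simple lineages, two niches."""
    counts = pd.DataFrame(
        {
            "s1": [2, 3, 5],
            "s2": [0, 1, 9],
            "s3": [4, 0, 6],
            "s4": [1, 1, 8],
        },
        index=["t1", "t2", "t3"],
    )
    taxonomy = pd.Series(
        {
            "t1": "Bacteria;P1;C1;O1;F1;G1",
            "t2": "Bacteria;P1;C1;O1;F1;G2",
            "t3": "Bacteria;P1;C1;O2;F2;G3",
        }
    )
    meta = make_metadata(
        ["s1", "s2", "s3", "s4"], ["bulk", "bulk", "rhizosphere", "root"]
    )
    return FeatureTable(counts=counts, taxonomy=taxonomy, metadata=meta)


@pytest.fixture(scope="session")
def canonical_community():
    """The canonical synthetic community (written by write_fixtures)."""
    return generate_community(GeneratorConfig(seed=FIXTURE_SEED))


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """Canonical fixture files on disk."""
    from rhizonet.synthetic_data import write_fixtures

    out = tmp_path_factory.mktemp("fixtures")
    write_fixtures(out)
    return out


def random_feature_table(rng, n_taxa=20, n_samples=9):
    """Small random table over three niches for property tests."""
    counts = pd.DataFrame(
        rng.integers(0, 20, size=(n_taxa, n_samples)),
        index=[f"t{i:02d}" for i in range(n_taxa)],
        columns=[f"s{j}" for j in range(n_samples)],
    )
    taxonomy = pd.Series(
        {f"t{i:02d}": f"Bacteria;P;C;O{i % 3};F{i % 5};G{i}" for i in range(n_taxa)}
    )
    niches = ["bulk", "rhizosphere", "root"] * (n_samples // 3)
    meta = make_metadata(list(counts.columns), niches)
    return FeatureTable(counts=counts, taxonomy=taxonomy, metadata=meta)
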