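import numpy as np
import pandas as pd
import pytest

from urbanbees.synthetic import generate_dataset, scenario


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small deterministic survey: (records, sites, traits)."""
    return generate_dataset(scenario("tiny", seed=42))


@pytest.fixture(scope="session")
def tiny_files(tmp_path_factory, tiny_dataset):
    records, sites, traits = tiny_dataset
    d = tmp_path_factory.mktemp("tiny")
    records.to_csv(d / "records.csv", index=False)
    sites.to_csv(d / "sites.csv", index=False)
    traits.to_csv(d / "traits.csv", index=False)
    return d / "records.csv", d / "sites.csv", d / "traits.csv"


@pytest.fixture()
def toy_sites():
    return pd.DataFrame(
        {
            "site_id": ["s1", "s2"],
            "x": [0.0, 1000.0],
            "y": [0.0, 0.0],
            "pop_density": [120.0, 8000.0],
            "impervious_pct": [5.0, 80.0],
            "region": ["Atlantic", "Continental"],
            "active_days": [3, 5],
            "passive_hours": [0.0, 24.0],
            "kick_net": [0, 1],
            "sampling_category": ["C0", "C1"],
        }
    )


@pytest.fixture()
def toy_records():
    return pd.DataFrame(
        {
            "site_id": ["s1", "s1", "s2"],
            "species": ["Bombus pascuorum", "Andrena flavipes", "Bombus pascuorum"],
            "count": [2, 1, 4],
            "year": [2015, 2015, 2016],
        }
    )


@pytest.fixture()
def toy_traits():
    return pd.DataFrame(
        {
            "species": ["Bombus pascuorum", "Andrena flavipes"],
            "nesting": ["above", "below"],
            "sociality": ["social", "solitary"],
            "diet": ["generalist", "specialist"],
            "size": ["large", "small"],
            "itd_mm": [4.2, 1.8],
            "parasitic": [False, False],
        }
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
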