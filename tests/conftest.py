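import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import dualtrace as dt

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_sim():
    """One default-condition experiment, shared across tests."""
    table, truth = dt.simulate_experiment(dt.SimulationConfig(seed=11))
    return table, truth


@pytest.fixture(scope="session")
def default_pipeline(default_sim):
    """Filtered table, pairs for both designs, library, quantification."""
    table, truth = default_sim
    table = dt.exclude_fed_precursors(dt.filter_rt_window(table))
    pairs_phe = dt.find_pairs(table, "Phe")
    pairs_tyr = dt.find_pairs(table, "Tyr")
    library = dt.build_library(pairs_phe, pairs_tyr, table)
    records = dt.quantify(table, library)
    return dict(table=table, truth=truth, pairs_phe=pairs_phe,
                pairs_tyr=pairs_tyr, library=library, records=records)


@pytest.fixture
def tiny_table():
    """Hand-written 2-feature, 4-sample table."""
    feats = pd.DataFrame({
        "feature_id": ["M310T325", "M121T468"],
        "mz": [310.0935, 121.0298],
        "rt": [325.0, 468.0],
        "s1": [100.0, 10.0],
        "s2": [110.0, 12.0],
        "s3": [95.0, 11.0],
        "s4": [105.0, 9.0],
    })
    meta = pd.DataFrame({
        "sample_id": ["s1", "s2", "s3", "s4"],
        "tissue": ["leaf"] * 4,
        "precursor": ["Phe", "Phe", "Tyr", "Tyr"],
        "isotope": ["12C", "13C", "12C", "13C"],
        "replicate": [1, 1, 1, 1],
    })
    return dt.validate_table(feats, meta)


def random_table(rng, n_features=20, n_samples=4):
    """Small random but valid feature table (for round-trip properties)."""
    mz = rng.uniform(100, 900, n_features)
    rt = rng.uniform(50, 1200, n_features)
    feats = pd.DataFrame({"mz": mz, "rt": rt})
    sids = [f"s{i}" for i in range(n_samples)]
    for s in sids:
        feats[s] = rng.uniform(0, 1e6, n_features)
    meta = pd.DataFrame({
        "sample_id": sids,
        "tissue": ["leaf"] * n_samples,
        "precursor": ["Phe", "Phe", "Tyr", "Tyr"][:n_samples],
        "isotope": ["12C", "13C"] * (n_samples // 2),
        "replicate": 1,
    })
    return dt.validate_table(feats, meta)
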