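import numpy as np
import pandas as pd
import pytest

from linkedscore.coding import MappingTable
from linkedscore.synthetic import GeneratorConfig, generate, survival_records


@pytest.fixture(scope="session")
def small_cohort():
    """A seeded 4,000-patient cohort with mixed null/non-null groups,
    shared across tests that only need a realistic linked cohort."""
    cfg = GeneratorConfig(
        n_patients=4000,
        seed=42,
        p0=0.6,
        baseline_hazard=0.0097,
        base_prevalence=0.04,
        severity_prevalence_factor=2.5,
    )
    patients, events, mapping_df, truth = generate(cfg)
    return {
        "config": cfg,
        "patients": patients,
        "events": events,
        "mapping_df": mapping_df,
        "mapping": MappingTable(
            dict(zip(mapping_df["icd_subchapter"], mapping_df["read_subchapter"]))
        ),
        "records": survival_records(patients),
        "truth": truth,
    }


@pytest.fixture(scope="session")
def published_table():
    from linkedscore import published_weight_table

    return published_weight_table()


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_records(n, seed=0, scale=1.0, censor=0.5):
    """Tiny random survival records for metric-level tests."""
    rng = np.random.default_rng(seed)
    t = np.ceil(rng.exponential(scale, n) * 30)
    e = rng.random(n) > censor
    return pd.DataFrame({"time": t, "event": e})
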