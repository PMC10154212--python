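import numpy as np
import pandas as pd
import pytest

from microaging.profiles import AbundanceTable, SampleMetadata, StudyCollection
from microaging.simulate import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_collection():
    """A modest multi-study synthetic collection with planted structure."""
    cfg = SyntheticConfig(
        n_studies=4,
        samples_per_study=(60, 80),
        n_taxa=30,
        n_health_core=6,
        n_disease_subhub_1=3,
        n_disease_subhub_2=3,
        depth=10_000,
        n_repositories=4,
        seed=7,
    )
    return generate_dataset(cfg)


def make_collection(tables: dict, ages: dict | None = None, data_types: dict | None = None,
                    repository: dict | None = None, extra_cols: dict | None = None):
    """Assemble a StudyCollection from raw per-study DataFrames."""
    abundance = {s: AbundanceTable(df, scale="counts") for s, df in tables.items()}
    rows = []
    for study, table in abundance.items():
        for i, sid in enumerate(table.sample_ids):
            row = dict(
                sample_id=sid,
                study_id=study,
                age=(ages or {}).get(sid, 50.0),
                data_type=(data_types or {}).get(study, "shotgun"),
                health_status="unknown",
            )
            for col, mapping in (extra_cols or {}).items():
                row[col] = mapping.get(sid, np.nan)
            rows.append(row)
    meta = SampleMetadata(pd.DataFrame(rows))
    return StudyCollection(tables=abundance, metadata=meta, repository=repository or {})
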