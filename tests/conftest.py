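import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from chemovar import ingest, synthetic

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config():
    """A compact synthetic study: 3 labs, all unit/isomer dialects."""
    return synthetic.GeneratorConfig(
        n_labs=3, n_producers=12, n_strains=9,
        samples_per_producer_strain=(2, 5), seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return synthetic.generate_dataset(small_config)


@pytest.fixture(scope="session")
def harmonized(small_dataset):
    batches, truth = small_dataset
    return ingest.harmonize(batches), truth


def make_lab_batch(rows: list[dict], lab_id="lab-x", unit="percent") -> ingest.LabBatch:
    """Small hand-built LabBatch for targeted filter/harmonization tests."""
    df = pd.DataFrame(rows)
    for col in ("sample_id", "producer_id", "strain_name", "category_label"):
        if col not in df.columns:
            df[col] = [f"{col}-{i}" for i in range(len(df))]
    return ingest.LabBatch(
        lab_id=lab_id, unit=unit, data=df, panel=ingest.infer_panel(df.columns)
    )


def clean_sample_row(i=0, **overrides) -> dict:
    """A QC-clean sample row over the full common panel."""
    row = {
        "sample_id": f"S{i:04d}",
        "producer_id": "p0",
        "strain_name": "alpha",
        "category_label": "Hybrid",
        "thca": 20.0 + 0.01 * i, "thc": 1.0,
        "cbda": 0.1, "cbd": 0.01,
        "cbga": 0.5, "cbg": 0.05,
        "cbca": 0.05, "cbc": 0.01,
        "cbna": 0.02, "cbn": 0.01,
        "thcva": 0.02, "thcv": 0.01,
        "alpha_pinene": 0.10, "alpha_terpinene": 0.01, "beta_pinene": 0.05,
        "bisabolol": 0.06, "camphene": 0.02, "caryophyllene": 0.55,
        "gamma_terpinene": 0.01, "humulene": 0.17, "limonene": 0.50,
        "linalool": 0.14, "myrcene": 0.30 + 0.001 * i, "nerolidol": 0.03,
        "ocimene": 0.04, "terpinolene": 0.02,
    }
    row.update(overrides)
    return row
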