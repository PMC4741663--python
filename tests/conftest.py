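import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from mirprofiler.core_io import ExpressionMatrix, SampleSheet
from mirprofiler.preprocess import floor_and_log, percentile_shift
from mirprofiler.synthetic import generate_dataset, planted_axis_design

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=60)
settings.load_profile("suite")


def make_matrix(values, probes=None, samples=None, scale="raw"):
    values = np.asarray(values, dtype=float)
    probes = probes or [f"p{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(
        data=pd.DataFrame(values, index=probes, columns=samples), scale_tag=scale
    )


def make_sheet(assignments):
    """assignments: dict sample_id -> class label."""
    return SampleSheet(
        data=pd.DataFrame(
            {"class_label": list(assignments.values())},
            index=pd.Index(list(assignments.keys()), name="sample_id"),
        )
    )


@pytest.fixture(scope="session")
def planted():
    """Full-size planted two-axis design (862 probes, 145/96/53) plus its
    preprocessed matrix; shared across tests as it is deterministic."""
    cfg = planted_axis_design(seed=3)
    ds = generate_dataset(cfg)
    normalized = percentile_shift(floor_and_log(ds.matrix))
    return cfg, ds, normalized


@pytest.fixture(scope="session")
def small_planted():
    """Scaled-down planted design for fast recovery checks."""
    cfg = planted_axis_design(
        n_probes=200,
        n_axis1=40,
        n_axis2=30,
        n_shared=15,
        n_up=(10, 4, 2),
        n_unlocalized=(6, 3),
        fragile_fraction=0.2,
        seed=11,
    )
    ds = generate_dataset(cfg)
    normalized = percentile_shift(floor_and_log(ds.matrix))
    return cfg, ds, normalized
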