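import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from imodkit import SyntheticSpec, simulate


@pytest.fixture(scope="session")
def small_spec():
    """A tiny but structured compendium: 3 modules, 300 genes, 36 samples."""
    return SyntheticSpec(
        n_genes=300,
        n_modules=3,
        module_size_min=8,
        module_size_max=15,
        n_projects=4,
        conditions_per_project=3,
        replicates_per_condition=3,
        activity_scale=10.0,
        replicate_noise_sd=1.0,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_bundle(small_spec):
    truth, expr = simulate(small_spec)
    return truth, expr


@pytest.fixture()
def toy_expression():
    """Hand-built 5-gene x 6-sample matrix: 2 projects x ref/test x 2 replicates-ish."""
    rng = np.random.default_rng(11)
    data = pd.DataFrame(
        rng.normal(5.0, 1.0, size=(5, 6)),
        index=[f"g{i}" for i in range(5)],
        columns=["a_ref1", "a_ref2", "a_t1", "a_t2", "b_ref1", "b_ref2"],
    )
    return data


@pytest.fixture()
def toy_metadata():
    return pd.DataFrame(
        {
            "sample_id": ["a_ref1", "a_ref2", "a_t1", "a_t2", "b_ref1", "b_ref2"],
            "project": ["A", "A", "A", "A", "B", "B"],
            "condition": ["ref", "ref", "test", "test", "ref", "ref"],
            "replicate_group": ["A_ref", "A_ref", "A_test", "A_test", "B_ref", "B_ref"],
            "is_reference": [True, True, False, False, True, True],
            "fallback_reference_project": [pd.NA] * 6,
        }
    )
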