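import numpy as np
import pandas as pd
import pytest

import devclock as dc
from devclock.synthetic import truth_annotation


@pytest.fixture()
def small_beta():
    return dc.BetaMatrix(
        ["cgA", "cgB", "cgC"],
        ["s1", "s2"],
        np.array([[0.1, 0.2], [0.3, 0.4], [0.5, 0.6]]),
    )


@pytest.fixture()
def small_sheet():
    return dc.SampleSheet(
        pd.DataFrame(
            {
                "sample_id": ["s1", "s2"],
                "age_value": [100.0, 120.0],
                "age_unit": ["dpc", "dpc"],
                "sex": ["female", "male"],
                "dataset_id": ["d1", "d1"],
                "group": ["fetal_brain", "fetal_brain"],
            }
        )
    )


@pytest.fixture(scope="session")
def sim_dataset():
    """A mid-sized age-structured simulation shared across tests."""
    spec = dc.SimSpec(n_samples=120, n_probes=600, n_age_probes=30, seed=7)
    betas, intens, sheet, truth = dc.simulate_age_dataset(spec)
    return betas, intens, sheet, truth, truth_annotation(truth)
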