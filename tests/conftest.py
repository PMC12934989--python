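import numpy as np
import pytest
from hypothesis import settings

import nichemet as nm

settings.register_profile("suite", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("suite")

COHORT_SEED = 11


@pytest.fixture(scope="session")
def default_cohort():
    """Default synthetic cohort (20 subjects, 64x64 grids, 60 features),
    segmented at K=4 with marker-based niche calling.  Shared session-wide
    because simulation + segmentation of 20 sections is the most expensive
    fixture in the suite."""
    params = nm.default_params(seed=COHORT_SEED)
    datasets, records, truth = nm.simulate_cohort(params)
    segs = {
        d.section_id: nm.segment_section(
            d, K=4, seed=COHORT_SEED + 100, markers=params.marker_features
        )
        for d in datasets
    }
    return {
        "params": params,
        "datasets": datasets,
        "records": records,
        "truth": truth,
        "segs": segs,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
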