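import numpy as np
import pandas as pd
import pytest

import omisurv as om


@pytest.fixture(scope="session")
def small_cohort():
    """An 80-sample cohort with moderate signal and some missingness."""
    cfg = om.SyntheticConfig(
        n_samples=80,
        n_features={"rna": 60, "mirna": 20, "methylation": 60},
        n_informative={"rna": 10, "mirna": 4, "methylation": 10},
        effect_size=1.0,
        hazard_ratio=2.0,
        missing_rate=0.05,
        seed=11,
    )
    return om.generate_cohort(cfg)


@pytest.fixture(scope="session")
def stacked_small(small_cohort):
    blocks, clinical, truth = small_cohort
    clean = {k: om.preprocess_block(b) for k, b in blocks.items()}
    stacked = om.stack_unit_norm([clean["rna"], clean["mirna"], clean["methylation"]])
    return stacked, clinical.subset(stacked.sample_ids), truth, clean


@pytest.fixture()
def tiny_clinical():
    """Six subjects, mixed events and censorings, no ties."""
    return om.ClinicalTable(
        pd.DataFrame(
            {
                "os_time": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
                "os_event": [1, 0, 1, 1, 0, 1],
            },
            index=pd.Index([f"s{i}" for i in range(6)], name="sample_id"),
        )
    )


def random_censored_clinical(rng, n):
    """Random survival data with exponential censoring, for oracle tests."""
    t_event = rng.exponential(1.0, n)
    t_cens = rng.exponential(1.5, n)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    return om.ClinicalTable(
        pd.DataFrame(
            {"os_time": time, "os_event": event},
            index=pd.Index([f"s{i}" for i in range(n)], name="sample_id"),
        )
    )
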