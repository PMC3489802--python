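import numpy as np
import pandas as pd
import pytest

from rarseek.core import ClinicalTable, ProbeMap
from rarseek.simulate import default_config, simulate_cohort


@pytest.fixture
def tiny_probe_map() -> ProbeMap:
    """Five handcrafted probes on two chromosomes."""
    return ProbeMap(
        probe_id=np.array(["p1", "p2", "p3", "p4", "p5"], dtype=object),
        chromosome=np.array(["1", "1", "1", "2", "2"], dtype=object),
        position=np.array([100, 500_000, 900_000, 200, 700_000]),
    )


@pytest.fixture
def tiny_clinical() -> ClinicalTable:
    return ClinicalTable(pd.DataFrame({
        "sample": ["S1", "S2", "S3", "S4"],
        "age_group": ["<50", ">=50", "<50", ">=50"],
        "stage": ["I", "IIA", "IIB", "I"],
        "er": ["positive", "negative", "positive", "negative"],
        "pr": ["negative", "negative", "positive", "negative"],
        "her2": ["negative", "positive", "positive", "negative"],
        "survival_years": [12.0, 3.5, 8.0, 10.0],
        "event": [0, 1, 0, 1],
    }))


@pytest.fixture(scope="session")
def small_cohort():
    """48-sample cohort restricted to chromosomes 16/17/20 at array density.

    Shared across tests that only need a realistic simulated cohort; the
    restriction keeps segmentation fast while preserving probe spacing.
    """
    cfg = default_config(seed=42, chromosomes=("16", "17", "20"))
    probes, matrix, clinical, truth = simulate_cohort(cfg)
    return cfg, probes, matrix, clinical, truth
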