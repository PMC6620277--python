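import numpy as np
import pandas as pd
import pytest

from pcnsl_immune import (
    ClinicalTable,
    ExpressionMatrix,
    SimulationConfig,
    load_panels,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def panels():
    return load_panels("pcnsl2019")


@pytest.fixture()
def random_expression():
    """Random 10-variant x 8-sample FPKM matrix, fixed seed."""
    rng = np.random.default_rng(42)
    data = pd.DataFrame(
        np.exp(rng.standard_normal((10, 8))),
        index=[f"GENE{i}-001" for i in range(10)],
        columns=[f"s{i}" for i in range(8)],
    )
    return ExpressionMatrix(data)


@pytest.fixture(scope="session")
def small_cohort():
    """60-patient synthetic cohort, Inhibitory-driven, seed 7."""
    cfg = SimulationConfig(n_samples=60, seed=7)
    cohort, truth = simulate_cohort(cfg)
    return cohort, truth


def make_clinical(times, events, samples=None):
    samples = samples or [f"s{i}" for i in range(len(times))]
    return ClinicalTable(pd.DataFrame({"os_days": times, "event": events}, index=samples))
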