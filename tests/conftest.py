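import numpy as np
import pandas as pd
import pytest

import hdxfda as h


def make_long_table(rows):
    """Rows of (seq, start, end, z, cond, rep, t, value)."""
    return pd.DataFrame(
        rows,
        columns=[
            "analyte_sequence", "start", "end", "charge", "condition",
            "replicate", "exposure_s", "value",
        ],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


@pytest.fixture(scope="session")
def small_simulated():
    """A 40-peptide two-condition simulated experiment, fixed seed."""
    scenario = h.Scenario(m=4, R=3, n_peptides=40, seed=101)
    return h.simulate_experiment(scenario)


@pytest.fixture(scope="session")
def small_results(small_simulated):
    dataset, _ = small_simulated
    return h.run_functional_test(dataset)


@pytest.fixture
def two_condition_dataset():
    """Noise-free curves from two visibly different kinetic parameter sets."""
    times = np.array([0.0, 30.0, 240.0, 1800.0, 14400.0])
    pa = h.KineticParams(a=8.0, b=0.01, q=1.0, d=1000.0)
    pb = h.KineticParams(a=4.0, b=0.001, q=1.0, d=1000.0)
    rows = []
    for cond, params in [("A", pa), ("B", pb)]:
        for rep in "12":
            for t in times:
                rows.append(
                    ("PEPTIDER", 1, 8, 1, cond, rep, t, h.evaluate_model(params, t))
                )
    return h.HDXDataset(make_long_table(rows))
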