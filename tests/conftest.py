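import numpy as np
import pandas as pd
import pytest

import acclimkit as ak


@pytest.fixture(scope="session")
def design144():
    """Canonical 144-sample factorial design."""
    return ak.canonical_design()


@pytest.fixture(scope="session")
def stressed72(design144):
    return design144.subset("condition == 'stressed'")


def toy_design(treatments, days, conditions=("stressed",), colonies=None):
    """Small hand-built design for enumeration tests.

    ``treatments``/``days``/``conditions`` are per-sample level lists of
    equal length.
    """
    n = len(treatments)
    df = pd.DataFrame(
        {
            "colony_id": colonies or [f"c{i}" for i in range(n)],
            "tank_id": "t1",
            "batch": 1,
            "treatment": list(treatments),
            "day": list(days),
            "condition": list(conditions) * (n if len(conditions) == 1 else 1),
        },
        index=pd.Index([f"s{i}" for i in range(n)], name="sample_id"),
    )
    return ak.ExperimentDesign(df)


@pytest.fixture
def design6():
    """6 samples: 3 treatments x 2 days, one replicate per cell."""
    return toy_design(
        treatments=["control29", "control29", "stable31", "stable31",
                    "variable29_33", "variable29_33"],
        days=[7, 11, 7, 11, 7, 11],
    )


@pytest.fixture
def design6_2x2():
    """6 samples: 2 treatments x 2 days with unbalanced cells (2,1,1,2)."""
    return toy_design(
        treatments=["control29", "control29", "control29",
                    "stable31", "stable31", "stable31"],
        days=[7, 7, 11, 7, 11, 11],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
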