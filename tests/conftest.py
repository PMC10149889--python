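import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from psyvalid import datasets

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from psyvalid.correlations import CorrelationMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20240117)


@pytest.fixture(scope="session")
def study1_convergent():
    return datasets.load_convergent("study1")


@pytest.fixture(scope="session")
def study2_convergent():
    return datasets.load_convergent("study2")


@pytest.fixture(scope="session")
def study1_net():
    """(block, domains) of the 30-correlate x 8-measure reference net."""
    return datasets.load_nomological("study1")


@pytest.fixture(scope="session")
def study2_net():
    return datasets.load_nomological("study2")


def make_symmetric(values, labels) -> CorrelationMatrix:
    frame = pd.DataFrame(np.asarray(values, dtype=float), index=labels, columns=labels)
    return CorrelationMatrix(values=frame, symmetric=True)


@pytest.fixture
def ratings_small():
    """Tiny long-format rating table: 3 targets, 2 measures, 1-3 informants."""
    rows = []
    scores = {
        0: {"self": 2.0, "informants": [1.0, 3.0]},
        1: {"self": 4.0, "informants": [4.0]},
        2: {"self": 3.0, "informants": [2.0, 3.0, 4.0]},
    }
    for t, d in scores.items():
        for m in ("A", "B"):
            shift = 0.0 if m == "A" else 1.0
            rows.append((t, f"self_{t}", "self", 1, m, d["self"] + shift))
            for i, s in enumerate(d["informants"]):
                rows.append((t, f"inf_{t}_{i}", "informant", 1, m, s + shift))
    return pd.DataFrame(rows, columns=["target", "rater", "role", "wave", "measure", "score"])
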