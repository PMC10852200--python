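import numpy as np
import pandas as pd
import pytest

from idakit import MonotherapyScreen


def make_screen(rows, lower_is_better=True, name="test"):
    """Build a screen from (model_id, drug, concentration, efficacy[, cancer_type]) tuples."""
    cols = ["model_id", "drug", "concentration", "efficacy"]
    if rows and len(rows[0]) == 5:
        cols.append("cancer_type")
    return MonotherapyScreen(
        data=pd.DataFrame(rows, columns=cols),
        lower_is_better=lower_is_better,
        name=name,
    )


def random_screen(rng, n_models=10, n_drugs=3, max_concs=3, lower_is_better=True):
    """A fully crossed random screen: every model measured for every drug at
    every dose, efficacies uniform in [0, 1]."""
    models = [f"L{i}" for i in range(n_models)]
    rows = []
    for d in range(n_drugs):
        drug = f"D{d}"
        concs = np.sort(rng.uniform(0.01, 10.0, size=rng.integers(1, max_concs + 1)))
        for c in concs:
            for m in models:
                rows.append((m, drug, float(c), float(rng.uniform(0.0, 1.0))))
    return make_screen(rows, lower_is_better=lower_is_better, name="random")


@pytest.fixture
def toy_screen():
    """Two models, two drugs, one dose each; per-model minima are 0.2 and 0.1."""
    return make_screen(
        [
            ("L1", "A", 1.0, 0.2),
            ("L2", "A", 1.0, 0.8),
            ("L1", "B", 2.0, 0.9),
            ("L2", "B", 2.0, 0.1),
        ]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
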