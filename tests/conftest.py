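import warnings

import numpy as np
import pandas as pd
import pytest

from qmpflow import quantify, synthio

warnings.filterwarnings("ignore", category=UserWarning)


def small_config(seed=42, **overrides):
    """Reduced-size study used by unit tests (full design, fewer taxa)."""
    defaults = dict(
        seed=seed,
        n_taxa_bacteria=40,
        n_taxa_fungi=25,
        n_metabolites=200,
        pattern_spec=synthio.PatternSpec(6, 5, 8),
    )
    defaults.update(overrides)
    return synthio.SimConfig(**defaults)


@pytest.fixture(scope="session")
def study():
    return synthio.simulate_study(small_config())


@pytest.fixture(scope="session")
def true_loads(study):
    return study.truth.loads.set_index("sample_id")["load"]


@pytest.fixture(scope="session")
def qmp_bacteria(study, true_loads):
    return quantify.qmp_transform(study.tables["bacteria"], true_loads)


@pytest.fixture(scope="session")
def rmp_bacteria(study):
    return quantify.rmp_transform(study.tables["bacteria"])


def dmm_counts(seed, n=150, p=50, depth=50000, k=3, conc=30):
    """Counts from k well-separated Dirichlet-multinomial components."""
    rng = np.random.default_rng(seed)
    means = rng.dirichlet(np.full(p, 0.1), size=k)
    labels = np.repeat(np.arange(k), n // k)
    x = np.zeros((n, p))
    for i, lab in enumerate(labels):
        theta = rng.dirichlet(np.maximum(means[lab] * conc, 1e-6))
        x[i] = rng.multinomial(depth, theta)
    return pd.DataFrame(x, index=[f"s{i}" for i in range(n)]), labels
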