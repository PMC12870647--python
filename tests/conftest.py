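import numpy as np
import pandas as pd
import pytest

from phenoconcord import example_catalog
from phenoconcord.instruments_io import ScoreTable, derive_totals
from phenoconcord.synthetic_data import default_cohort_config, generate_score_table


@pytest.fixture(scope="session")
def catalog():
    return example_catalog()


@pytest.fixture(scope="session")
def small_cohort(catalog):
    """Study-shaped synthetic cohort, n=300, fixed seed."""
    cfg = default_cohort_config(catalog, n_participants=300, seed=11)
    return generate_score_table(cfg, catalog)


def make_two_cluster_table(catalog, n=1000, separation=10.0, noise_sd=1.0,
                           seed=0, independent=False):
    """Score table whose ADOS and ADIR sub-scores carry a 2-group structure.

    Both instruments are driven by the same group labels unless
    ``independent`` is set, in which case each instrument gets its own
    labels.  ``separation`` is in units of the within-group noise sd.
    """
    rng = np.random.default_rng(seed)
    g_a = rng.integers(0, 2, size=n)
    g_b = g_a if not independent else rng.integers(0, 2, size=n)
    cols = {}
    for sub in catalog.subscore_ids("ADOS"):
        cols[sub] = np.round(g_a * separation * noise_sd
                             + rng.normal(0, noise_sd, n)).astype(int)
    for sub in catalog.subscore_ids("ADIR"):
        cols[sub] = np.round(g_b * separation * noise_sd
                             + rng.normal(0, noise_sd, n)).astype(int)
    values = pd.DataFrame(cols, index=[f"P{i}" for i in range(n)])
    return ScoreTable(values=values, totals=derive_totals(values, catalog))
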