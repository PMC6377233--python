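import numpy as np
import pandas as pd
import pytest

from lunaromics import design as dz
from lunaromics import synth


@pytest.fixture(scope="session")
def study_design():
    return dz.make_study_design()


@pytest.fixture(scope="session")
def tmt_design():
    return dz.make_tmt_design()


@pytest.fixture(scope="session")
def small_config():
    return synth.SimConfig(n_transcripts=300, n_proteins=120, seed=123)


@pytest.fixture(scope="session")
def small_counts(small_config, study_design):
    counts, ledger = synth.simulate_counts(small_config, study_design)
    return counts, ledger


@pytest.fixture(scope="session")
def small_tmt(small_config, tmt_design):
    peptides, ledger = synth.simulate_tmt(small_config, tmt_design)
    return peptides, ledger


def brute_force_bh(p):
    """Independent step-up BH oracle (textbook formulation)."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running_min = np.inf
    for rank_from_top in range(m, 0, -1):
        idx = order[rank_from_top - 1]
        running_min = min(running_min, p[idx] * m / rank_from_top)
        adj[idx] = min(running_min, 1.0)
    return adj


def enumerate_hypergeom_over(n_universe, big_k, n_draw, x):
    """P(X >= x) by exhaustive enumeration of all n-subsets (tiny universes)."""
    from itertools import combinations

    universe = range(n_universe)
    term = set(range(big_k))
    total = 0
    hits = 0
    for draw in combinations(universe, n_draw):
        total += 1
        if len(term & set(draw)) >= x:
            hits += 1
    return hits / total


def enumerate_hypergeom_under(n_universe, big_k, n_draw, x):
    from itertools import combinations

    universe = range(n_universe)
    term = set(range(big_k))
    total = 0
    hits = 0
    for draw in combinations(universe, n_draw):
        total += 1
        if len(term & set(draw)) <= x:
            hits += 1
    return hits / total


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
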