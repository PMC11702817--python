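"""Shared fixtures: the ground-truth network, sampled cohorts, and a
random-network generator used by the inference-oracle property tests."""
from __future__ import annotations

import numpy as np
import pytest

from contextrisk.bayesnet import CPT, DAG, BayesNet, EdgeBlacklist, fit_parameters, learn_structure
from contextrisk.cohort import UNKNOWN, VariableSpec
from contextrisk.evaluation import SplitSpec, split
from contextrisk.synthetic import TruthConfig, make_truth_network, sample_cohort

OUTCOME = "morbidity"


@pytest.fixture(scope="session")
def truth_net() -> BayesNet:
    return make_truth_network(TruthConfig())


@pytest.fixture(scope="session")
def truth_net_null() -> BayesNet:
    """Control network without the fetal-sex x diabetes interaction."""
    return make_truth_network(TruthConfig().without_interaction())


@pytest.fixture(scope="session")
def cohort_20k(truth_net):
    return sample_cohort(truth_net, 20_000, seed=420)


@pytest.fixture(scope="session")
def cohort_50k(truth_net):
    return sample_cohort(truth_net, 50_000, seed=421)


@pytest.fixture(scope="session")
def outcome_terminal_blacklist(truth_net) -> EdgeBlacklist:
    """Clinical constraint: the composite outcome cannot be a cause."""
    return EdgeBlacklist.of(
        *[(OUTCOME, v) for v in truth_net.dag.nodes if v != OUTCOME]
    )


@pytest.fixture(scope="session")
def structure_runs(truth_net, outcome_terminal_blacklist):
    """Structure learning at n=50,000 over three simulation seeds.

    Shared between the adjacency-recovery and AUC-fidelity checks.
    Each entry: (seed, derivation, validation, learned DAG, fitted net).
    """
    runs = []
    for seed in (1, 2, 3):
        cohort = sample_cohort(truth_net, 50_000, seed=500 + seed)
        derivation, validation = split(cohort, SplitSpec(seed=seed))
        dag = learn_structure(
            derivation, blacklist=outcome_terminal_blacklist, seed=seed, restarts=10
        )
        net = fit_parameters(dag, derivation, method="bayes", alpha=1.0)
        runs.append((seed, derivation, validation, dag, net))
    return runs


def random_network(rng: np.random.Generator, n_nodes: int | None = None) -> BayesNet:
    """A random DAG with random Dirichlet CPTs over 2-3-state variables.

    Joint state space is kept small enough for brute-force enumeration.
    """
    if n_nodes is None:
        n_nodes = int(rng.integers(3, 11))
    names = [f"v{i}" for i in range(n_nodes)]
    order = rng.permutation(n_nodes)
    cards = rng.integers(2, 4, size=n_nodes)
    while np.prod(cards.astype(float)) > 5e5:
        cards[rng.integers(n_nodes)] = 2
    edges = []
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < 0.3:
                edges.append((names[order[i]], names[order[j]]))
    specs = {}
    for name, card in zip(names, cards):
        observed = tuple(f"s{k}" for k in range(card - 1))
        specs[name] = VariableSpec(name, observed + (UNKNOWN,))
    dag = DAG(names, edges)
    cpts = {}
    for name in names:
        parents = dag.parents(name)
        r = specs[name].n_states
        q = int(np.prod([specs[p].n_states for p in parents])) if parents else 1
        rows = rng.dirichlet(np.ones(r) * 0.8, size=q)
        shape = tuple(specs[p].n_states for p in parents) + (r,)
        cpts[name] = CPT(name, parents, rows.reshape(shape))
    return BayesNet(dag, cpts, specs)
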