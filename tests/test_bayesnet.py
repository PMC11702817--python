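"""Network core: BIC scoring, hill-climbing search, blacklists, parameter fits."""
import math

import numpy as np
import pandas as pd
import pytest

from contextrisk.bayesnet import (
    CPT,
    DAG,
    BayesNet,
    DAGError,
    EdgeBlacklist,
    bic_score,
    blacklist_from_families,
    fit_parameters,
    learn_structure,
)
from contextrisk.cohort import BINARY_STATES, UNKNOWN, Cohort, VariableSpec, binary_spec


def _binary_cohort(columns: dict[str, list[str]], outcome: str | None = None) -> Cohort:
    df = pd.DataFrame(columns)
    outcome = outcome or list(columns)[-1]
    specs = {c: binary_spec(c) for c in columns}
    return Cohort(df, outcome, specs)


# -- DAG ---------------------------------------------------------------------

def test_dag_rejects_cycles_self_edges_duplicates():
    with pytest.raises(DAGError):
        DAG(["a", "b"], [("a", "b"), ("b", "a")])
    with pytest.raises(DAGError):
        DAG(["a"], [("a", "a")])
    with pytest.raises(DAGError):
        DAG(["a", "b"], [("a", "b"), ("a", "b")])


def test_dag_topological_order_and_adjacency():
    dag = DAG(["c", "a", "b"], [("a", "b"), ("b", "c")])
    order = dag.topological_order()
    assert order.index("a") < order.index("b") < order.index("c")
    assert dag.adjacencies() == frozenset({frozenset({"a", "b"}), frozenset({"b", "c"})})


# -- BIC ---------------------------------------------------------------------

def test_bic_single_node_closed_form():
    """Counts (6 present, 4 absent), N=10: 6 ln .6 + 4 ln .4 - (1/2) ln 10."""
    cohort = _binary_cohort({"x": ["present"] * 6 + ["absent"] * 4})
    expected = 6 * math.log(0.6) + 4 * math.log(0.4) - 0.5 * math.log(10)
    assert bic_score(DAG(["x"]), cohort) == pytest.approx(expected, abs=1e-12)


def test_adding_edge_never_decreases_likelihood_term():
    rng = np.random.default_rng(4)
    x = rng.integers(0, 2, 500)
    y = rng.integers(0, 2, 500)
    states = np.array(["absent", "present"])
    cohort = _binary_cohort({"x": list(states[x]), "y": list(states[y])})
    n = cohort.n
    empty, single = DAG(["x", "y"]), DAG(["x", "y"], [("x", "y")])
    # strip the dimension penalties to compare raw fitted log-likelihoods
    ll_empty = bic_score(empty, cohort) + 0.5 * 2 * math.log(n)
    ll_single = bic_score(single, cohort) + 0.5 * 3 * math.log(n)
    assert ll_single >= ll_empty - 1e-9


def test_bic_consistency_empty_graph_wins_on_independent_data():
    rng = np.random.default_rng(5)
    states = np.array(["absent", "present"])
    cols = {c: list(states[rng.integers(0, 2, 50_000)]) for c in "abc"}
    cohort = _binary_cohort(cols)
    empty = DAG(["a", "b", "c"])
    for edge in [("a", "b"), ("b", "c"), ("a", "c")]:
        assert bic_score(empty, cohort) >= bic_score(empty.with_edge(*edge), cohort)


def test_bic_score_equivalence_of_reversed_edge():
    rng = np.random.default_rng(6)
    x = rng.integers(0, 2, 2000)
    y = np.where(rng.random(2000) < 0.8, x, 1 - x)
    states = np.array(["absent", "present"])
    cohort = _binary_cohort({"x": list(states[x]), "y": list(states[y])})
    fwd = bic_score(DAG(["x", "y"], [("x", "y")]), cohort)
    rev = bic_score(DAG(["x", "y"], [("y", "x")]), cohort)
    assert fwd == pytest.approx(rev, abs=1e-9)


# -- structure search --------------------------------------------------------

def test_structure_recovery_of_planted_dependence():
    rng = np.random.default_rng(7)
    a = rng.integers(0, 2, 50_000)
    b = np.where(rng.random(50_000) < 0.9, a, 1 - a)
    states = np.array(["absent", "present"])
    cohort = _binary_cohort({"a": list(states[a]), "b": list(states[b])})
    dag = learn_structure(cohort, seed=0, restarts=3)
    assert frozenset({"a", "b"}) in dag.adjacencies()


def test_independent_variables_give_empty_graph():
    rng = np.random.default_rng(8)
    states = np.array(["absent", "present"])
    cols = {c: list(states[rng.integers(0, 2, 20_000)]) for c in "abcd"}
    dag = learn_structure(_binary_cohort(cols), seed=0, restarts=2)
    assert len(dag.edges) == 0


def test_blacklist_blocks_deterministically_related_pair():
    """Even perfectly dependent variables stay unlinked when both edge
    directions are blacklisted (mutually exclusive one-hot siblings)."""
    rng = np.random.default_rng(9)
    early = rng.integers(0, 2, 5000)
    term = 1 - early
    states = np.array(["absent", "present"])
    cohort = _binary_cohort(
        {"early_ptb": list(states[early]), "term": list(states[term])}
    )
    bl = EdgeBlacklist.of(("early_ptb", "term"), ("term", "early_ptb"))
    dag = learn_structure(cohort, blacklist=bl, seed=0, restarts=2)
    assert len(dag.edges) == 0


def test_learned_graph_always_acyclic_and_blacklist_respecting():
    rng = np.random.default_rng(10)
    states = np.array(["absent", "present"])
    names = [f"v{i}" for i in range(6)]
    for trial in range(10):
        base = rng.integers(0, 2, (300, 6))
        base[:, 1] = np.where(rng.random(300) < 0.7, base[:, 0], base[:, 1])
        cohort = _binary_cohort({n: list(states[base[:, i]]) for i, n in enumerate(names)})
        forbidden = {
            (names[int(rng.integers(6))], names[int(rng.integers(6))]) for _ in range(4)
        }
        forbidden = {(p, c) for p, c in forbidden if p != c}
        bl = EdgeBlacklist(frozenset(forbidden))
        dag = learn_structure(cohort, blacklist=bl, seed=trial, restarts=3)
        dag.topological_order()  # raises on cycles
        assert not (dag.edges & bl.forbidden)
        assert bic_score(dag, cohort) >= bic_score(DAG(names), cohort) - 1e-9


def test_learn_structure_deterministic_given_seed(cohort_20k):
    small = cohort_20k.subset(np.arange(cohort_20k.n) < 5000)
    a = learn_structure(small, seed=3, restarts=3)
    b = learn_structure(small, seed=3, restarts=3)
    assert a == b


def test_node_budget_enforced():
    rng = np.random.default_rng(11)
    states = np.array(["absent", "present"])
    cols = {f"v{i}": list(states[rng.integers(0, 2, 20)]) for i in range(20)}
    with pytest.raises(DAGError):
        learn_structure(_binary_cohort(cols))


# -- family blacklists -------------------------------------------------------

def test_blacklist_from_families_counts():
    ga = {f"ga_{s}": VariableSpec(f"ga_{s}", BINARY_STATES, family="ga") for s in "abc"}
    efw = {f"efw_{s}": VariableSpec(f"efw_{s}", BINARY_STATES, family="efw") for s in "abcd"}
    none = {"x": binary_spec("x")}
    assert len(blacklist_from_families(ga).forbidden) == 6
    assert len(blacklist_from_families(none).forbidden) == 0
    assert len(blacklist_from_families({**ga, **efw}).forbidden) == 18


# -- parameter estimation ----------------------------------------------------

def test_fit_parameters_closed_forms():
    cohort = _binary_cohort({"x": ["present"] * 6 + ["absent"] * 4})
    dag = DAG(["x"])
    mle = fit_parameters(dag, cohort, method="mle")
    assert mle.cpts["x"].values[:2] == pytest.approx([0.4, 0.6])
    # symmetric Dirichlet alpha=1 over r=3 states (absent, present, unknown)
    bayes = fit_parameters(dag, cohort, method="bayes", alpha=1.0)
    assert bayes.cpts["x"].values == pytest.approx([5 / 13, 7 / 13, 1 / 13])


def test_unobserved_parent_configuration_uniform_fallback():
    cohort = _binary_cohort(
        {"p": ["absent"] * 10, "c": ["present"] * 5 + ["absent"] * 5}
    )
    net = fit_parameters(DAG(["p", "c"], [("p", "c")]), cohort, method="mle")
    # parent states "present" and "unknown" were never observed
    assert net.uniform_rows["c"] == 2
    assert net.cpts["c"].values[1] == pytest.approx([1 / 3, 1 / 3, 1 / 3])


def test_fit_parameter_validation():
    cohort = _binary_cohort({"x": ["present", "absent"]})
    with pytest.raises(ValueError):
        fit_parameters(DAG(["x"]), cohort, method="bayes", alpha=0.0)
    with pytest.raises(ValueError):
        fit_parameters(DAG(["x"]), cohort, method="map")


# -- serialization -----------------------------------------------------------

def test_network_json_roundtrip(truth_net, tmp_path):
    path = tmp_path / "net.json"
    truth_net.to_json(path)
    back = BayesNet.from_json(path)
    assert back.dag == truth_net.dag
    for node in truth_net.dag.nodes:
        assert np.allclose(back.cpts[node].values, truth_net.cpts[node].values)
        assert back.specs[node].states == truth_net.specs[node].states
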