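"""Feature selection: association ranking, redundancy pruning, ROC
thresholds, and the k-of-m combination search."""
import math

import numpy as np
import pandas as pd
import pytest

from contextrisk.cohort import Cohort, UNKNOWN, binary_spec
from contextrisk.features import (
    FeatureSelectionError,
    assemble_pgm_features,
    derive_threshold,
    jaccard,
    prune_redundant,
    rank_features,
    search_combinations,
)


def _cohort(columns: dict[str, list[str]], outcome: str = "y", ranks: dict | None = None) -> Cohort:
    specs = {
        c: binary_spec(c, clinical_rank=(ranks or {}).get(c)) for c in columns
    }
    return Cohort(pd.DataFrame(columns), outcome, specs)


def _states(bits) -> list[str]:
    return ["present" if b else "absent" for b in bits]


# -- ranking -----------------------------------------------------------------

def test_perfect_predictor_mi_equals_outcome_entropy():
    rng = np.random.default_rng(0)
    y = rng.integers(0, 2, 2000)
    cohort = _cohort({"x": _states(y), "y": _states(y)})
    ranking = rank_features(cohort)
    p = y.mean()
    h = -(p * math.log2(p) + (1 - p) * math.log2(1 - p))
    assert ranking["x"].mi == pytest.approx(h, abs=1e-12)
    assert ranking["x"].chi2_p < 1e-10


def test_independent_predictor_has_negligible_mi():
    rng = np.random.default_rng(1)
    y = rng.integers(0, 2, 50_000)
    x = rng.integers(0, 2, 50_000)
    ranking = rank_features(_cohort({"x": _states(x), "y": _states(y)}))
    assert ranking["x"].mi < 0.001  # plug-in MI bias bound at this n


def test_chi2_matches_hand_pearson_formula():
    """2x2 table (a=30, b=10, c=10, d=50) against the textbook formula."""
    x = _states([1] * 40 + [0] * 60)
    y = _states([1] * 30 + [0] * 10 + [1] * 10 + [0] * 50)
    ranking = rank_features(_cohort({"x": x, "y": y}))
    table = np.array([[50, 10], [10, 30]], dtype=float)
    n = table.sum()
    expected = np.outer(table.sum(1), table.sum(0)) / n
    chi2 = ((table - expected) ** 2 / expected).sum()
    assert ranking["x"].chi2_stat == pytest.approx(chi2, rel=1e-12)


def test_degenerate_single_state_variable_flagged():
    ranking = rank_features(
        _cohort({"x": ["absent"] * 10, "y": _states([0, 1] * 5)})
    )
    assert ranking["x"].degenerate
    assert ranking["x"].mi == 0.0 and ranking["x"].chi2_stat == 0.0


def test_unknowns_excluded_pairwise():
    y = _states([1, 1, 0, 0, 0, 0])
    x = ["present", "present", "absent", "absent", UNKNOWN, UNKNOWN]
    ranking = rank_features(_cohort({"x": x, "y": y}))
    # on the 4 complete pairs, x predicts y perfectly
    assert ranking["x"].mi == pytest.approx(1.0, abs=1e-12)


def test_combined_rank_is_permutation():
    rng = np.random.default_rng(2)
    y = rng.integers(0, 2, 500)
    cols = {"y": _states(y)}
    for i in range(5):
        noise = np.where(rng.random(500) < 0.1 * i, 1 - y, y)
        cols[f"x{i}"] = _states(noise)
    ranking = rank_features(_cohort(cols))
    assert sorted(ranking.table.combined_rank) == [1, 2, 3, 4, 5]


# -- redundancy pruning ------------------------------------------------------

def test_jaccard_set_arithmetic():
    a = np.zeros(200, dtype=bool)
    b = np.zeros(200, dtype=bool)
    a[:50] = True
    b[:100] = True  # A subset of B: |A n B| / |A u B| = 50/100
    assert jaccard(a, b) == 0.5
    assert jaccard(np.zeros(5, bool), np.zeros(5, bool)) == 0.0


def test_identical_columns_keep_clinically_preferred():
    rng = np.random.default_rng(3)
    y = rng.integers(0, 2, 300)
    x = _states(y)
    cohort = _cohort(
        {"research_def": x, "clinical_def": list(x), "y": _states(y)},
        ranks={"clinical_def": 1},
    )
    ranking = rank_features(cohort)
    kept = prune_redundant(ranking, cohort, threshold=0.8)
    assert "clinical_def" in kept and "research_def" not in kept


def test_disjoint_columns_both_retained():
    a = _states([1, 1, 0, 0])
    b = _states([0, 0, 1, 1])
    cohort = _cohort({"a": a, "b": b, "y": _states([1, 0, 1, 0])})
    kept = prune_redundant(rank_features(cohort), cohort, threshold=0.5)
    assert set(kept) == {"a", "b"}


def test_prune_is_order_invariant():
    rng = np.random.default_rng(4)
    y = rng.integers(0, 2, 400)
    cols = {}
    for i in range(6):
        cols[f"x{i}"] = _states(np.where(rng.random(400) < 0.2, 1 - y, y))
    cols["x_dup"] = list(cols["x0"])
    cols["y"] = _states(y)
    cohort = _cohort(cols)
    kept_fwd = prune_redundant(rank_features(cohort), cohort, 0.9)
    shuffled = _cohort({k: cols[k] for k in reversed(list(cols))})
    kept_rev = prune_redundant(rank_features(shuffled), shuffled, 0.9)
    assert set(kept_fwd) == set(kept_rev)


# -- ROC thresholds ----------------------------------------------------------

def test_threshold_perfect_separation():
    values = [1, 2, 3, 4]
    outcome = _states([0, 0, 1, 1])
    assert derive_threshold(values, outcome) == 3


def test_threshold_worked_example_by_exhaustive_scan():
    values = [1, 2, 3, 4, 5, 6]
    outcome_bits = [0, 0, 1, 0, 1, 1]
    outcome = _states(outcome_bits)
    y = np.array(outcome_bits)
    best_c, best_j = None, -np.inf
    for c in values:  # independent brute force over all candidate cutpoints
        pred = np.array(values) >= c
        j = (pred & (y == 1)).sum() / 3 + (~pred & (y == 0)).sum() / 3 - 1
        if j > best_j + 1e-12:
            best_c, best_j = c, j
    assert derive_threshold(values, outcome) == best_c == 3


def test_threshold_independent_outcome_near_zero_j():
    rng = np.random.default_rng(5)
    values = list(rng.random(2000))
    outcome = _states(rng.integers(0, 2, 2000))
    c = derive_threshold(values, outcome)
    y = np.array([o == "present" for o in outcome])
    pred = np.array(values) >= c
    j = (pred & y).sum() / y.sum() + (~pred & ~y).sum() / (~y).sum() - 1
    assert j < 0.1


def test_threshold_errors():
    with pytest.raises(FeatureSelectionError):
        derive_threshold([1, 1, 1], _states([0, 1, 0]))
    with pytest.raises(FeatureSelectionError):
        derive_threshold([1, 2, 3], _states([1, 1, 1]))


# -- combination search ------------------------------------------------------

@pytest.fixture(scope="module")
def planted_two_driver_cohort():
    rng = np.random.default_rng(6)
    n = 20_000
    x = rng.integers(0, 2, (n, 4))
    logit = -2.5 + 2.0 * x[:, 0] + 1.5 * x[:, 1]
    y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(int)
    cols = {f"x{i}": _states(x[:, i]) for i in range(4)}
    cols["y"] = _states(y)
    return _cohort(cols)


def test_exhaustive_search_finds_planted_drivers(planted_two_driver_cohort):
    result = search_combinations(
        planted_two_driver_cohort, [f"x{i}" for i in range(4)], 2, mode="exhaustive"
    )
    assert set(result.feature_set) == {"x0", "x1"}
    assert result.n_evaluated == 6


def test_exhaustive_best_beats_every_other_subset(planted_two_driver_cohort):
    from itertools import combinations

    feats = [f"x{i}" for i in range(4)]
    best = search_combinations(planted_two_driver_cohort, feats, 2, mode="exhaustive")
    for subset in combinations(feats, 2):
        single = search_combinations(
            planted_two_driver_cohort, list(subset), 2, mode="exhaustive"
        )
        assert best.auc >= single.auc - 1e-12


def test_k_equals_m_trivial(planted_two_driver_cohort):
    result = search_combinations(
        planted_two_driver_cohort, ["x0", "x1"], 2, mode="exhaustive"
    )
    assert result.feature_set == ("x0", "x1") and result.n_evaluated == 1


def test_exhaustive_refuses_thirty_choose_twelve():
    rng = np.random.default_rng(7)
    cols = {f"x{i:02d}": _states(rng.integers(0, 2, 40)) for i in range(30)}
    cols["y"] = _states(rng.integers(0, 2, 40))
    cohort = _cohort(cols)
    with pytest.raises(FeatureSelectionError, match="86493225"):
        search_combinations(cohort, [f"x{i:02d}" for i in range(30)], 12, mode="exhaustive")


def test_sampled_and_greedy_modes_deterministic(planted_two_driver_cohort):
    feats = [f"x{i}" for i in range(4)]
    a = search_combinations(planted_two_driver_cohort, feats, 2, mode="sampled", n_subsets=4, seed=3)
    b = search_combinations(planted_two_driver_cohort, feats, 2, mode="sampled", n_subsets=4, seed=3)
    assert a.feature_set == b.feature_set
    g = search_combinations(planted_two_driver_cohort, feats, 2, mode="greedy")
    assert set(g.feature_set) == {"x0", "x1"}


# -- final assembly ----------------------------------------------------------

def test_assemble_union_semantics(planted_two_driver_cohort):
    final = assemble_pgm_features(
        planted_two_driver_cohort, ["x0", "x1"], forced_includes=["x1", "x2"]
    )
    assert final == ["x0", "x1", "x2"]


def test_assemble_forced_only(planted_two_driver_cohort):
    # x3 is independent of the outcome, so only forced terms survive
    final = assemble_pgm_features(
        planted_two_driver_cohort, ["x3"], forced_includes=["x0"]
    )
    assert "x0" in final


def test_assemble_respects_node_budget(planted_two_driver_cohort):
    forced = [f"f{i}" for i in range(25)]
    with pytest.raises(FeatureSelectionError):
        assemble_pgm_features(planted_two_driver_cohort, ["x0"], forced_includes=forced)
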