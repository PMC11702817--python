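"""Risk analysis: scenario queries, bootstrap intervals, sequences,
alternate targets, and interaction scanning."""
import numpy as np
import pandas as pd
import pytest

from contextrisk.bayesnet import CPT, DAG, BayesNet, fit_parameters
from contextrisk.cohort import Cohort, binary_spec
from contextrisk.inference import InconsistentEvidenceError, brute_force_query, query
from contextrisk.risk import (
    BACKGROUND,
    Scenario,
    absolute_risk,
    alternate_target_panel,
    bootstrap_ci,
    estimate_risk,
    n_matching,
    relative_risk,
    scan_interactions,
    scenario_sequence,
)
from contextrisk.synthetic import sample_cohort

OUTCOME = "morbidity"


@pytest.fixture(scope="module")
def constructed_net():
    """S -> M with P(M|S=present)=0.2 and marginal background 0.1."""
    p_s = 0.5
    p_m = np.zeros((3, 3))
    p_m[1] = [0.8, 0.2, 0.0]  # given S present
    p_m[0] = [1.0, 0.0, 0.0]
    p_m[2] = [1 / 3, 1 / 3, 1 / 3]
    # background = 0.5*0.2 = 0.1
    dag = DAG(["s", "m"], [("s", "m")])
    specs = {"s": binary_spec("s"), "m": binary_spec("m")}
    cpts = {"s": CPT("s", (), np.array([0.5, 0.5, 0.0])), "m": CPT("m", ("s",), p_m)}
    return BayesNet(dag, cpts, specs)


# -- absolute and relative risk ----------------------------------------------

def test_background_scenario_risk_is_marginal(truth_net):
    assert absolute_risk(truth_net, BACKGROUND, OUTCOME) == pytest.approx(
        query(truth_net, OUTCOME)["present"], abs=1e-12
    )


def test_d_separated_scenario_leaves_risk_unchanged(truth_net):
    sc = Scenario("bp", {"bp_high": "present"})
    assert absolute_risk(truth_net, sc, OUTCOME) == pytest.approx(
        absolute_risk(truth_net, BACKGROUND, OUTCOME), abs=1e-12
    )
    assert relative_risk(truth_net, sc, OUTCOME) == pytest.approx(1.0, abs=1e-12)


def test_scenario_risk_matches_enumeration_oracle(truth_net):
    sc = Scenario(
        "EFW 3-9th + diabetes", {"efw": "p3to9", "diabetes": "present"}
    )
    oracle = brute_force_query(truth_net, OUTCOME, sc.evidence)["present"]
    assert absolute_risk(truth_net, sc, OUTCOME) == pytest.approx(oracle, abs=1e-10)


def test_constructed_rr_is_two(constructed_net):
    sc = Scenario("exposed", {"s": "present"})
    assert relative_risk(constructed_net, sc, "m") == pytest.approx(2.0, abs=1e-12)


def test_rr_of_reference_is_one_and_ratio_algebra(truth_net):
    ref = Scenario("ref", {"efw": "p3to9"})
    assert relative_risk(truth_net, ref, OUTCOME, ref) == pytest.approx(1.0)
    sc = Scenario("sc", {"efw": "p3to9", "diabetes": "present"})
    vs_bg = relative_risk(truth_net, sc, OUTCOME)
    vs_ref = relative_risk(truth_net, sc, OUTCOME, ref)
    ref_vs_bg = relative_risk(truth_net, ref, OUTCOME)
    assert vs_bg == pytest.approx(vs_ref * ref_vs_bg, rel=1e-12)


def test_inconsistent_scenario_raises(constructed_net):
    sc = Scenario("impossible", {"s": "unknown"})
    with pytest.raises(InconsistentEvidenceError, match="impossible"):
        absolute_risk(constructed_net, sc, "m")


# -- bootstrap ---------------------------------------------------------------

def test_bootstrap_degenerate_cohort_zero_width(truth_net):
    row = sample_cohort(truth_net, 1, seed=1).records
    df = pd.concat([row] * 50, ignore_index=True)
    cohort = Cohort(df, OUTCOME, {n: truth_net.specs[n] for n in truth_net.dag.nodes})
    res = bootstrap_ci(
        cohort,
        truth_net.dag,
        lambda m: query(m, OUTCOME)["present"],
        b=50,
        seed=0,
    )
    assert res.high - res.low == pytest.approx(0.0, abs=1e-12)


def test_bootstrap_seed_deterministic(truth_net, cohort_20k):
    small = cohort_20k.subset(np.arange(cohort_20k.n) < 2000)
    fn = lambda m: query(m, OUTCOME)["present"]
    a = bootstrap_ci(small, truth_net.dag, fn, b=100, seed=9)
    b = bootstrap_ci(small, truth_net.dag, fn, b=100, seed=9)
    assert (a.low, a.high) == (b.low, b.high)


def test_bootstrap_interval_shrinks_with_n(truth_net):
    fn = lambda m: query(m, OUTCOME)["present"]
    widths = []
    for n in (2_000, 20_000, 200_000):
        cohort = sample_cohort(truth_net, n, seed=n)
        res = bootstrap_ci(cohort, truth_net.dag, fn, b=100, seed=1)
        widths.append(res.high - res.low)
    assert widths[0] > widths[1] > widths[2]


# -- risk estimates and sequences --------------------------------------------

def test_estimate_risk_counts_matching_records(truth_net, cohort_20k):
    small = cohort_20k.subset(np.arange(cohort_20k.n) < 5000)
    sc = Scenario("female", {"female": "present"})
    est = estimate_risk(truth_net, small, truth_net.dag, sc, OUTCOME, b=50, seed=2)
    oracle = int((small.records["female"] == "present").sum())
    assert est.n_matching == oracle == n_matching(small, sc.evidence)
    assert est.ar_ci[0] <= est.ar_ci[1]


def test_scenario_sequence_monotone_on_planted_stack(truth_net, cohort_20k):
    small = cohort_20k.subset(np.arange(cohort_20k.n) < 2000)
    base = Scenario("EFW 3-9th", {"efw": "p3to9"})
    rows = scenario_sequence(
        truth_net,
        small,
        truth_net.dag,
        base,
        [("diabetes", "present"), ("anomaly", "present"), ("female", "present")],
        OUTCOME,
        b=50,
        seed=3,
    )
    ars = [r.ar for r in rows]
    assert len(rows) == 4
    assert all(b >= a - 1e-12 for a, b in zip(ars, ars[1:]))
    # each AR agrees with the enumeration oracle
    evidence = dict(base.evidence)
    for row, extra in zip(rows, [None, ("diabetes", "present"), ("anomaly", "present"), ("female", "present")]):
        if extra:
            evidence[extra[0]] = extra[1]
        oracle = brute_force_query(truth_net, OUTCOME, evidence)["present"]
        assert row.ar == pytest.approx(oracle, abs=1e-10)
    # n_matching may legitimately reach zero for the rare stack
    assert rows[-1].n_matching == n_matching(small, evidence)


def test_scenario_sequence_empty_additions(truth_net, cohort_20k):
    small = cohort_20k.subset(np.arange(cohort_20k.n) < 1000)
    rows = scenario_sequence(
        truth_net, small, truth_net.dag, BACKGROUND, [], OUTCOME, b=50, seed=4
    )
    assert len(rows) == 1 and rows[0].rr == pytest.approx(1.0)


# -- alternate targets -------------------------------------------------------

def test_alternate_target_panel_matches_standalone(truth_net, cohort_20k):
    small = cohort_20k.subset(np.arange(cohort_20k.n) < 2000)
    sc = Scenario("diabetes", {"diabetes": "present"})
    panel = alternate_target_panel(
        truth_net, small, truth_net.dag, sc, ["apgar_lt7", "urgent_cesarean", "bp_high"],
        b=50, seed=5,
    )
    for est in panel:
        standalone = query(truth_net, est.target, sc.evidence)["present"]
        assert est.ar == pytest.approx(standalone, abs=1e-12)
    # bp_high has no path to diabetes: RR exactly 1
    bp = [e for e in panel if e.target == "bp_high"][0]
    assert bp.rr == pytest.approx(1.0, abs=1e-12)


def test_swapped_roles_run_without_refitting(truth_net):
    """Former predictors can be queried as targets given the outcome."""
    res = query(truth_net, "efw", {OUTCOME: "present"})
    oracle = brute_force_query(truth_net, "efw", {OUTCOME: "present"})
    for s in truth_net.states("efw"):
        assert res[s] == pytest.approx(oracle[s], abs=1e-10)


def test_panel_rejects_target_in_evidence(truth_net, cohort_20k):
    sc = Scenario("ga", {"ga": "term"})
    with pytest.raises(ValueError):
        alternate_target_panel(
            truth_net, cohort_20k, truth_net.dag, sc, ["ga"], b=10, seed=0
        )


# -- interaction scanning ----------------------------------------------------

def test_scan_recovers_planted_reversal(truth_net, cohort_50k):
    findings = scan_interactions(
        truth_net, cohort_50k, truth_net.dag, "female", ["diabetes"], OUTCOME,
        b=150, seed=6,
    )
    assert len(findings) == 1
    f = findings[0]
    assert (f.effect_var, f.context_var, f.flag) == ("female", "diabetes", "reversal")
    assert f.stratum_estimates["present"][0] > 1 > f.stratum_estimates["absent"][0]


def test_scan_negative_control_finds_nothing(truth_net_null):
    cohort = sample_cohort(truth_net_null, 50_000, seed=60)
    findings = scan_interactions(
        truth_net_null, cohort, truth_net_null.dag, "female", ["diabetes"], OUTCOME,
        b=150, seed=7,
    )
    assert findings == []


def test_scan_identical_strata_not_flagged(truth_net, cohort_50k):
    """A context variable with no pathway to the outcome yields identical
    stratum RRs and no finding."""
    findings = scan_interactions(
        truth_net, cohort_50k, truth_net.dag, "female", ["bp_high"], OUTCOME,
        b=100, seed=8,
    )
    assert findings == []
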