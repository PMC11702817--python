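"""Clinical risk outputs: scenario queries, bootstrap intervals,
scenario sequences, alternate-target panels, and interaction scanning.

Absolute risk (AR) is the model's exact conditional probability of the
outcome given a scenario's evidence; relative risk (RR) is the ratio of
two ARs, typically scenario versus the model's background (empty
evidence) marginal.  Confidence intervals come from nonparametric
bootstrap: rows are resampled with replacement, parameters are refitted
on the fixed learned structure, and the query is recomputed; the
2.5th/97.5th percentiles of the replicate distribution form the 95%
interval.  Point estimates are the fitted model's own estimates, not
bootstrap means, so they need not sit at the interval's centre.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .bayesnet import BayesNet, DAG, ParamFitter
from .cohort import Cohort, UNKNOWN
from .inference import Evidence, InconsistentEvidenceError, query

__all__ = [
    "Scenario",
    "RiskEstimate",
    "BootstrapResult",
    "InteractionFinding",
    "absolute_risk",
    "relative_risk",
    "bootstrap_ci",
    "estimate_risk",
    "scenario_sequence",
    "alternate_target_panel",
    "scan_interactions",
]

BACKGROUND_LABEL = "background"


@dataclass(frozen=True)
class Scenario:
    """A labelled partial assignment used as query evidence."""

    label: str
    evidence: Mapping[str, str] = field(default_factory=dict)

    def extended(self, label: str, extra: Mapping[str, str]) -> "Scenario":
        merged = {**self.evidence, **extra}
        return Scenario(label, merged)


BACKGROUND = Scenario(BACKGROUND_LABEL, {})


@dataclass
class BootstrapResult:
    low: float
    high: float
    samples: np.ndarray
    n_failed: int = 0

    def overlaps(self, other: "BootstrapResult") -> bool:
        return self.low <= other.high and other.low <= self.high


@dataclass
class RiskEstimate:
    """Absolute and relative risk for one scenario and target."""

    label: str
    target: str
    ar: float
    ar_ci: tuple[float, float]
    rr: float
    rr_ci: tuple[float, float]
    reference: str
    n_matching: int
    b: int
    rr_vs_base: float | None = None
    rr_vs_base_ci: tuple[float, float] | None = None

    def as_row(self) -> dict:
        row = {
            "scenario": self.label,
            "target": self.target,
            "ar_pct": 100 * self.ar,
            "ar_low_pct": 100 * self.ar_ci[0],
            "ar_high_pct": 100 * self.ar_ci[1],
            "rr": self.rr,
            "rr_low": self.rr_ci[0],
            "rr_high": self.rr_ci[1],
            "reference": self.reference,
            "n_matching": self.n_matching,
            "b": self.b,
        }
        if self.rr_vs_base is not None:
            row["rr_vs_base"] = self.rr_vs_base
            row["rr_vs_base_low"] = self.rr_vs_base_ci[0]
            row["rr_vs_base_high"] = self.rr_vs_base_ci[1]
        return row


@dataclass
class InteractionFinding:
    effect_var: str
    context_var: str
    stratum_estimates: dict[str, tuple[float, BootstrapResult]]  # state -> (RR, CI)
    flag: str  # "reversal" | "magnitude"


def absolute_risk(net: BayesNet, scenario: Scenario, target: str) -> float:
    """P(target = present | scenario evidence), by exact inference."""
    if "present" not in net.specs[target].states:
        raise ValueError(
            f"risk target {target!r} is not binary-like (no 'present' state); "
            "one-hot expand multi-state variables first"
        )
    try:
        return query(net, target, scenario.evidence)["present"]
    except InconsistentEvidenceError:
        raise InconsistentEvidenceError(
            f"scenario {scenario.label!r} is inconsistent: evidence "
            f"{dict(scenario.evidence)} has zero probability"
        ) from None


def relative_risk(
    net: BayesNet, scenario: Scenario, target: str, reference: Scenario = BACKGROUND
) -> float:
    """AR(scenario) / AR(reference); the default reference is the model's
    background (empty-evidence) marginal."""
    ref = absolute_risk(net, reference, target)
    if ref == 0:
        raise ZeroDivisionError(f"reference scenario {reference.label!r} has zero risk")
    return absolute_risk(net, scenario, target) / ref


def n_matching(cohort: Cohort, evidence: Evidence) -> int:
    """Count of cohort records consistent with the evidence (unknown
    states matched literally)."""
    mask = np.ones(cohort.n, dtype=bool)
    for var, state in evidence.items():
        mask &= (cohort.records[var] == state).to_numpy()
    return int(mask.sum())


# ---------------------------------------------------------------------------
# Bootstrap machinery
# ---------------------------------------------------------------------------

def bootstrap_replicates(
    cohort: Cohort,
    dag: DAG,
    query_fns: Sequence[Callable[[BayesNet], float]],
    b: int = 1000,
    seed: int = 0,
    method: str = "mle",
    alpha: float = 1.0,
) -> tuple[np.ndarray, int]:
    """Shared bootstrap replicate matrix for several query functions.

    Each replicate resamples N rows with replacement, refits parameters
    on the fixed structure, and evaluates every query function.  A
    replicate in which any query is inconsistent (zero evidence mass) is
    recorded as missing and excluded; the count is returned.
    """
    if b < 2:
        raise ValueError("b must be at least 2")
    fitter = ParamFitter(dag, cohort)
    rng = np.random.default_rng(seed)
    out = np.full((b, len(query_fns)), np.nan)
    for i in range(b):
        rows = rng.integers(0, cohort.n, cohort.n)
        net = fitter.fit(rows=rows, method=method, alpha=alpha)
        try:
            out[i] = [fn(net) for fn in query_fns]
        except (InconsistentEvidenceError, ZeroDivisionError):
            continue
    ok = ~np.isnan(out).any(axis=1)
    return out[ok], int(b - ok.sum())


def _percentile_ci(samples: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    lo = 100 * (1 - level) / 2
    return (
        float(np.percentile(samples, lo)),
        float(np.percentile(samples, 100 - lo)),
    )


def bootstrap_ci(
    cohort: Cohort,
    dag: DAG,
    query_fn: Callable[[BayesNet], float],
    b: int = 1000,
    seed: int = 0,
    method: str = "mle",
    alpha: float = 1.0,
    level: float = 0.95,
) -> BootstrapResult:
    """Percentile bootstrap interval for one model-derived quantity;
    deterministic given the seed."""
    samples, n_failed = bootstrap_replicates(
        cohort, dag, [query_fn], b=b, seed=seed, method=method, alpha=alpha
    )
    low, high = _percentile_ci(samples[:, 0], level)
    return BootstrapResult(low, high, samples[:, 0], n_failed)


def estimate_risk(
    net: BayesNet,
    cohort: Cohort,
    dag: DAG,
    scenario: Scenario,
    target: str,
    reference: Scenario = BACKGROUND,
    base: Scenario | None = None,
    b: int = 1000,
    seed: int = 0,
    method: str = "mle",
    alpha: float = 1.0,
) -> RiskEstimate:
    """Point AR/RR from the fitted network plus bootstrap 95% CIs.

    ``reference`` names the RR denominator (background by default); an
    optional ``base`` scenario adds a second RR column (e.g. "versus
    non-severe FGR alone")."""
    ar = absolute_risk(net, scenario, target)
    rr = relative_risk(net, scenario, target, reference)
    fns: list[Callable[[BayesNet], float]] = [
        lambda m: absolute_risk(m, scenario, target),
        lambda m: relative_risk(m, scenario, target, reference),
    ]
    if base is not None:
        fns.append(lambda m: relative_risk(m, scenario, target, base))
    samples, _ = bootstrap_replicates(
        cohort, dag, fns, b=b, seed=seed, method=method, alpha=alpha
    )
    est = RiskEstimate(
        label=scenario.label,
        target=target,
        ar=ar,
        ar_ci=_percentile_ci(samples[:, 0]),
        rr=rr,
        rr_ci=_percentile_ci(samples[:, 1]),
        reference=reference.label,
        n_matching=n_matching(cohort, scenario.evidence),
        b=b,
    )
    if base is not None:
        est.rr_vs_base = relative_risk(net, scenario, target, base)
        est.rr_vs_base_ci = _percentile_ci(samples[:, 2])
    return est


def scenario_sequence(
    net: BayesNet,
    cohort: Cohort,
    dag: DAG,
    base_scenario: Scenario,
    added_factors: Sequence[tuple[str, str]],
    target: str,
    b: int = 1000,
    seed: int = 0,
    method: str = "mle",
    alpha: float = 1.0,
) -> list[RiskEstimate]:
    """Sequential introduction of clinical factors onto a base scenario.

    One row per cumulative scenario (base; base+f1; base+f1+f2; ...)
    reporting AR, RR versus background, RR versus the base scenario, and
    the count of derivation-cohort records matching the evidence (which
    may legitimately be zero: the model still yields an estimate)."""
    rows: list[RiskEstimate] = []
    current = base_scenario
    rows.append(
        estimate_risk(
            net, cohort, dag, current, target, b=b, seed=seed, method=method, alpha=alpha
        )
    )
    for i, (var, state) in enumerate(added_factors):
        current = current.extended(f"{current.label} + {var}={state}", {var: state})
        rows.append(
            estimate_risk(
                net,
                cohort,
                dag,
                current,
                target,
                base=base_scenario,
                b=b,
                seed=seed + i + 1,
                method=method,
                alpha=alpha,
            )
        )
    return rows


def alternate_target_panel(
    net: BayesNet,
    cohort: Cohort,
    dag: DAG,
    scenario: Scenario,
    targets: Sequence[str],
    comparator: Scenario | None = None,
    b: int = 1000,
    seed: int = 0,
    method: str = "mle",
    alpha: float = 1.0,
) -> list[RiskEstimate]:
    """Risk of several alternate targets under one scenario.

    Any network variable can serve as the query target without
    refitting; each entry reports AR and RR versus background (and
    versus an optional comparator scenario)."""
    out = []
    for i, target in enumerate(targets):
        if target in scenario.evidence:
            raise ValueError(f"target {target!r} appears in the scenario evidence")
        out.append(
            estimate_risk(
                net,
                cohort,
                dag,
                scenario,
                target,
                base=comparator,
                b=b,
                seed=seed + i,
                method=method,
                alpha=alpha,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Interaction (effect modification) scanning
# ---------------------------------------------------------------------------

def scan_interactions(
    net: BayesNet,
    cohort: Cohort,
    dag: DAG,
    effect_var: str,
    context_vars: Sequence[str],
    target: str,
    base_evidence: Mapping[str, str] | None = None,
    strata_defs: Mapping[str, Mapping[str, Mapping[str, str]]] | None = None,
    b: int = 200,
    seed: int = 0,
    method: str = "mle",
    alpha: float = 1.0,
    effect_state: str = "present",
    reference_state: str = "absent",
) -> list[InteractionFinding]:
    """Detect effect modification of ``effect_var`` by each context variable.

    Within every stratum of a context variable the RR of the outcome for
    the effect variable's level versus its reference level is computed
    with a bootstrap CI (replicates shared across strata).  A finding is
    flagged whenever two strata have non-overlapping 95% intervals;
    ``"reversal"`` when additionally the point estimates of RR - 1
    change sign, ``"magnitude"`` otherwise.  A stratum whose evidence
    has zero mass is skipped and reported via a warning.
    """
    import warnings as _warnings

    base_evidence = dict(base_evidence or {})
    findings: list[InteractionFinding] = []
    for context_var in context_vars:
        if strata_defs and context_var in strata_defs:
            strata = {k: dict(v) for k, v in strata_defs[context_var].items()}
        else:
            strata = {
                state: {**base_evidence, context_var: state}
                for state in net.specs[context_var].observed_states
            }

        def stratum_rr(m: BayesNet, ev: Mapping[str, str]) -> float:
            num = query(m, target, {**ev, effect_var: effect_state})["present"]
            den = query(m, target, {**ev, effect_var: reference_state})["present"]
            if den == 0:
                raise ZeroDivisionError
            return num / den

        points: dict[str, float] = {}
        valid: dict[str, Mapping[str, str]] = {}
        for state, ev in strata.items():
            try:
                points[state] = stratum_rr(net, ev)
                valid[state] = ev
            except (InconsistentEvidenceError, ZeroDivisionError):
                _warnings.warn(
                    f"stratum {context_var}={state} has zero evidence mass; skipped"
                )
        if len(valid) < 2:
            continue
        names = list(valid)
        fns = [
            (lambda m, ev=valid[s]: stratum_rr(m, ev)) for s in names
        ]
        samples, _ = bootstrap_replicates(
            cohort, dag, fns, b=b, seed=seed, method=method, alpha=alpha
        )
        cis = {
            s: BootstrapResult(*_percentile_ci(samples[:, i]), samples[:, i])
            for i, s in enumerate(names)
        }
        flagged = None
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                a, bb = names[i], names[j]
                if not cis[a].overlaps(cis[bb]):
                    reversal = (points[a] - 1) * (points[bb] - 1) < 0
                    if reversal:
                        flagged = "reversal"
                    elif flagged is None:
                        flagged = "magnitude"
        if flagged:
            findings.append(
                InteractionFinding(
                    effect_var=effect_var,
                    context_var=context_var,
                    stratum_estimates={s: (points[s], cis[s]) for s in names},
                    flag=flagged,
                )
            )
    return findings
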