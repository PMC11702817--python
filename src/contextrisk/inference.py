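"""Exact probabilistic inference on a discrete Bayesian network.

Conditional queries run by variable elimination with a min-fill
ordering; a brute-force full-joint enumeration oracle is provided for
cross-checking.  Evidence on the ``"unknown"`` state is conditioned on
literally — missingness is a learned state of the model, and training
and inference must agree on its meaning.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .bayesnet import BayesNet
from .cohort import Cohort, UNKNOWN

__all__ = [
    "Evidence",
    "QueryResult",
    "InconsistentEvidenceError",
    "joint_probability",
    "query",
    "brute_force_query",
    "predict",
    "predict_batch",
]

_BRUTE_FORCE_LIMIT = 10**7


class InferenceError(ValueError):
    pass


class InconsistentEvidenceError(InferenceError):
    """The evidence has probability zero under the model."""


Evidence = Mapping[str, str]


@dataclass(frozen=True)
class QueryResult:
    target: str
    distribution: dict[str, float]
    evidence_mass: float

    def __getitem__(self, state: str) -> float:
        return self.distribution[state]


def _validate_evidence(net: BayesNet, evidence: Evidence, target: str | None = None) -> None:
    for node, state in evidence.items():
        if node not in net.specs:
            raise InferenceError(f"evidence node {node!r} not in network")
        net.state_index(node, state)  # raises on invalid state
    if target is not None:
        if target not in net.specs:
            raise InferenceError(f"target {target!r} not in network")
        if target in evidence:
            raise InferenceError(f"target {target!r} may not appear in evidence")


def joint_probability(net: BayesNet, assignment: Evidence) -> float:
    """Probability of one full assignment: the product of CPT entries."""
    missing = set(net.dag.nodes) - set(assignment)
    if missing:
        raise InferenceError(f"assignment must cover all nodes; missing {sorted(missing)}")
    _validate_evidence(net, assignment)
    prob = 1.0
    for node in net.dag.nodes:
        cpt = net.cpts[node]
        idx = tuple(net.state_index(p, assignment[p]) for p in cpt.parents)
        prob *= float(cpt.values[idx + (net.state_index(node, assignment[node]),)])
    return prob


# ---------------------------------------------------------------------------
# Factor machinery
# ---------------------------------------------------------------------------

def _reduced_factors(net: BayesNet, evidence: Evidence) -> list[tuple[tuple[str, ...], np.ndarray]]:
    factors = []
    for node in net.dag.nodes:
        cpt = net.cpts[node]
        axes = cpt.parents + (node,)
        arr = cpt.values
        keep: list[str] = []
        for i, var in enumerate(axes):
            if var in evidence:
                arr = np.take(arr, net.state_index(var, evidence[var]), axis=len(keep))
            else:
                keep.append(var)
        factors.append((tuple(keep), arr))
    return factors


def _multiply(factors: Sequence[tuple[tuple[str, ...], np.ndarray]]) -> tuple[tuple[str, ...], np.ndarray]:
    """Multiply factors into one array over the union of their scopes."""
    axis_of: dict[str, int] = {}
    for vars_, _ in factors:
        for v in vars_:
            if v not in axis_of:
                axis_of[v] = len(axis_of)
    operands = []
    for vars_, arr in factors:
        operands.append(arr)
        operands.append([axis_of[v] for v in vars_])
    out_axes = list(range(len(axis_of)))
    result = np.einsum(*operands, out_axes, optimize=True)
    order = tuple(sorted(axis_of, key=axis_of.get))
    return order, result


def _eliminate(factors: list[tuple[tuple[str, ...], np.ndarray]], var: str) -> list[tuple[tuple[str, ...], np.ndarray]]:
    touching = [f for f in factors if var in f[0]]
    rest = [f for f in factors if var not in f[0]]
    vars_, arr = _multiply(touching)
    arr = arr.sum(axis=vars_.index(var))
    rest.append((tuple(v for v in vars_ if v != var), arr))
    return rest


def _min_fill_order(scopes: list[set[str]], to_eliminate: set[str]) -> list[str]:
    scopes = [set(s) for s in scopes]
    order: list[str] = []
    remaining = set(to_eliminate)
    while remaining:
        best_var, best_key = None, None
        for v in sorted(remaining):
            neighbors: set[str] = set()
            for s in scopes:
                if v in s:
                    neighbors |= s
            neighbors.discard(v)
            # fill-in edges introduced by eliminating v
            nb = sorted(neighbors)
            fill = 0
            for i in range(len(nb)):
                for j in range(i + 1, len(nb)):
                    if not any(nb[i] in s and nb[j] in s for s in scopes):
                        fill += 1
            key = (fill, len(nb), v)
            if best_key is None or key < best_key:
                best_var, best_key = v, key
        assert best_var is not None
        merged: set[str] = set()
        new_scopes = []
        for s in scopes:
            if best_var in s:
                merged |= s
            else:
                new_scopes.append(s)
        merged.discard(best_var)
        new_scopes.append(merged)
        scopes = new_scopes
        order.append(best_var)
        remaining.discard(best_var)
    return order


def query(net: BayesNet, target: str, evidence: Evidence | None = None) -> QueryResult:
    """Exact conditional distribution of ``target`` given partial evidence.

    Variable elimination with a min-fill ordering.  Raises
    :class:`InconsistentEvidenceError` when the evidence has zero
    probability under the model.
    """
    evidence = dict(evidence or {})
    _validate_evidence(net, evidence, target)
    factors = _reduced_factors(net, evidence)
    hidden = set(net.dag.nodes) - set(evidence) - {target}
    order = _min_fill_order([set(f[0]) for f in factors], hidden)
    for var in order:
        factors = _eliminate(factors, var)
    vars_, arr = _multiply(factors)
    if vars_ == ():
        raise InferenceError("no target axis left")  # pragma: no cover
    vec = arr if vars_ == (target,) else np.moveaxis(arr, vars_.index(target), 0)
    mass = float(vec.sum())
    if mass <= 0.0:
        raise InconsistentEvidenceError(
            f"evidence {evidence} has zero probability under the model"
        )
    dist = vec / mass
    states = net.states(target)
    return QueryResult(target, {s: float(dist[i]) for i, s in enumerate(states)}, mass)


def brute_force_query(net: BayesNet, target: str, evidence: Evidence | None = None) -> QueryResult:
    """Exact conditional by full-joint enumeration (test oracle).

    Refuses when the joint state space exceeds 10^7 configurations.
    """
    evidence = dict(evidence or {})
    _validate_evidence(net, evidence, target)
    space = 1
    for node in net.dag.nodes:
        if node not in evidence:
            space *= net.card(node)
        if space > _BRUTE_FORCE_LIMIT:
            raise InferenceError(
                f"joint state space exceeds {_BRUTE_FORCE_LIMIT} configurations"
            )
    factors = _reduced_factors(net, evidence)
    vars_, joint = _multiply(factors)
    axis = vars_.index(target)
    other = tuple(i for i in range(joint.ndim) if i != axis)
    vec = joint.sum(axis=other) if other else joint
    mass = float(vec.sum())
    if mass <= 0.0:
        raise InconsistentEvidenceError(
            f"evidence {evidence} has zero probability under the model"
        )
    dist = vec / mass
    states = net.states(target)
    return QueryResult(target, {s: float(dist[i]) for i, s in enumerate(states)}, mass)


# ---------------------------------------------------------------------------
# Prediction
# ---------------------------------------------------------------------------

def predict(net: BayesNet, record: Evidence, target: str, state: str = "present") -> float:
    """P(target = state | all non-target assignments of one record).

    ``"unknown"`` cells are conditioned on as the unknown state,
    consistent with how the network was trained.
    """
    evidence = {k: v for k, v in record.items() if k != target and k in net.specs}
    return query(net, target, evidence)[state]


def predict_batch(
    net: BayesNet, cohort: Cohort, target: str, state: str = "present"
) -> np.ndarray:
    """Vectorised per-record prediction over a cohort.

    Because every non-target node is observed, the conditional reduces to
    normalising the joint factorisation over the target's states; this is
    exact and O(rows x nodes).
    """
    if target not in net.specs:
        raise InferenceError(f"target {target!r} not in network")
    index = {v: i for i, v in enumerate(cohort.variables)}
    for node in net.dag.nodes:
        if node != target and node not in index:
            raise InferenceError(f"cohort lacks column {node!r}")
    codes = cohort.codes()
    n = cohort.n
    r = net.card(target)
    logp = np.zeros((n, r))
    tiny = 1e-300
    for node in net.dag.nodes:
        cpt = net.cpts[node]
        axes = cpt.parents + (node,)
        logv = np.log(np.maximum(cpt.values, tiny))
        idx: list[np.ndarray] = []
        target_axis = None
        for ax, var in enumerate(axes):
            if var == target:
                target_axis = ax
                idx.append(np.zeros(n, dtype=np.int64))  # placeholder
            else:
                idx.append(codes[:, index[var]])
        if target_axis is None:
            logp += logv[tuple(idx)][:, None]
        else:
            for s in range(r):
                idx[target_axis] = np.full(n, s, dtype=np.int64)
                logp[:, s] += logv[tuple(idx)]
    logp -= logp.max(axis=1, keepdims=True)
    p = np.exp(logp)
    total = p.sum(axis=1)
    if (total <= 0).any():
        raise InconsistentEvidenceError("a record has zero probability under the model")
    return p[:, net.state_index(target, state)] / total
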