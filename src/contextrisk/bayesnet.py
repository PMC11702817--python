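"""Discrete Bayesian network core.

DAG and conditional-probability-table (CPT) types, BIC scoring,
greedy hill-climbing structure search honouring edge blacklists, and
parameter estimation (maximum-likelihood and Dirichlet-smoothed).

Conventions
-----------
* Natural logarithms throughout; BIC(G) = log L_hat - (d/2) ln N with
  d = sum over nodes of (r_i - 1) * q_i, where r_i is the node's state
  count and q_i the number of parent configurations.  Higher is better
  and the score decomposes node-wise.
* ``"unknown"`` is an ordinary state wherever it occurs in the data.
  Structure scoring uses *effective* cardinalities (states actually
  observed in the cohort) so that declared-but-unseen states do not
  inflate the dimension penalty; fitted CPTs always span the full
  declared state space.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from itertools import permutations
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from .cohort import Cohort, VariableSpec

__all__ = [
    "DAG",
    "CPT",
    "BayesNet",
    "EdgeBlacklist",
    "bic_score",
    "learn_structure",
    "blacklist_from_families",
    "fit_parameters",
]


class DAGError(ValueError):
    pass


class DAG:
    """A directed acyclic graph over named nodes."""

    def __init__(self, nodes: Sequence[str], edges: Iterable[tuple[str, str]] = ()):
        self.nodes: tuple[str, ...] = tuple(nodes)
        if len(set(self.nodes)) != len(self.nodes):
            raise DAGError("duplicate node names")
        node_set = set(self.nodes)
        edge_list = [tuple(e) for e in edges]
        if len(set(edge_list)) != len(edge_list):
            raise DAGError("duplicate edges")
        for p, c in edge_list:
            if p == c:
                raise DAGError(f"self-edge {p}->{c}")
            if p not in node_set or c not in node_set:
                raise DAGError(f"edge {p}->{c} references unknown node")
        self.edges: frozenset[tuple[str, str]] = frozenset(edge_list)
        self._parents: dict[str, tuple[str, ...]] = {n: () for n in self.nodes}
        self._children: dict[str, list[str]] = {n: [] for n in self.nodes}
        for p, c in sorted(self.edges):
            self._parents[c] = tuple(sorted(self._parents[c] + (p,)))
            self._children[p].append(c)
        self.topological_order()  # raises on cycles

    def parents(self, node: str) -> tuple[str, ...]:
        return self._parents[node]

    def children(self, node: str) -> tuple[str, ...]:
        return tuple(self._children[node])

    def has_edge(self, parent: str, child: str) -> bool:
        return (parent, child) in self.edges

    def _reachable(self, src: str, dst: str) -> bool:
        """True if dst is reachable from src by directed edges."""
        stack, seen = [src], set()
        while stack:
            u = stack.pop()
            if u == dst:
                return True
            for v in self._children[u]:
                if v not in seen:
                    seen.add(v)
                    stack.append(v)
        return False

    def would_cycle(self, parent: str, child: str) -> bool:
        """Would adding parent -> child create a directed cycle?"""
        return self._reachable(child, parent)

    def topological_order(self) -> tuple[str, ...]:
        indeg = {n: len(self._parents[n]) for n in self.nodes}
        frontier = sorted(n for n, d in indeg.items() if d == 0)
        order: list[str] = []
        while frontier:
            u = frontier.pop(0)
            order.append(u)
            for v in self._children[u]:
                indeg[v] -= 1
                if indeg[v] == 0:
                    # insertion keeps frontier sorted -> deterministic order
                    lo = 0
                    while lo < len(frontier) and frontier[lo] < v:
                        lo += 1
                    frontier.insert(lo, v)
        if len(order) != len(self.nodes):
            raise DAGError("graph contains a cycle")
        return tuple(order)

    def adjacencies(self) -> frozenset[frozenset[str]]:
        """Undirected skeleton, for structure-recovery comparison."""
        return frozenset(frozenset(e) for e in self.edges)

    def with_edge(self, parent: str, child: str) -> "DAG":
        return DAG(self.nodes, self.edges | {(parent, child)})

    def without_edge(self, parent: str, child: str) -> "DAG":
        return DAG(self.nodes, self.edges - {(parent, child)})

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(sorted(self.edges))
        return g

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, DAG)
            and self.nodes == other.nodes
            and self.edges == other.edges
        )

    def __hash__(self) -> int:
        return hash((self.nodes, self.edges))

    def __repr__(self) -> str:
        return f"DAG({len(self.nodes)} nodes, {len(self.edges)} edges)"


@dataclass(frozen=True)
class EdgeBlacklist:
    """Directed edges the structure search must never add."""

    forbidden: frozenset[tuple[str, str]] = frozenset()

    def __contains__(self, edge: tuple[str, str]) -> bool:
        return tuple(edge) in self.forbidden

    def validate(self, nodes: Sequence[str]) -> None:
        unknown = {n for e in self.forbidden for n in e} - set(nodes)
        if unknown:
            raise DAGError(f"blacklist references unknown nodes {sorted(unknown)}")

    @classmethod
    def of(cls, *edges: tuple[str, str]) -> "EdgeBlacklist":
        return cls(frozenset(tuple(e) for e in edges))

    def union(self, other: "EdgeBlacklist") -> "EdgeBlacklist":
        return EdgeBlacklist(self.forbidden | other.forbidden)


def terminal_node_blacklist(nodes: Sequence[str], terminal: str) -> EdgeBlacklist:
    """Forbid every edge out of a terminal node (e.g. the composite
    outcome, which cannot act as a cause of antecedent variables)."""
    return EdgeBlacklist(frozenset((terminal, n) for n in nodes if n != terminal))


def blacklist_from_families(specs: Mapping[str, VariableSpec]) -> EdgeBlacklist:
    """Forbid both directed edges within every one-hot family.

    Mutually exclusive siblings (e.g. the gestational-age categories) are
    deterministically related, so edges among them would only encode the
    encoding itself.
    """
    families: dict[str, list[str]] = {}
    for name, spec in specs.items():
        if spec.family is not None:
            families.setdefault(spec.family, []).append(name)
    forbidden = set()
    for members in families.values():
        for a, b in permutations(sorted(members), 2):
            forbidden.add((a, b))
    return EdgeBlacklist(frozenset(forbidden))


@dataclass
class CPT:
    """Conditional probability table for one node.

    ``values`` has one axis per parent (in ``parents`` order, each axis
    length = that parent's state count) plus a trailing axis over the
    node's own states.  Every row sums to one.
    """

    node: str
    parents: tuple[str, ...]
    values: np.ndarray

    def validate(self) -> None:
        rows = self.values.reshape(-1, self.values.shape[-1])
        if not np.allclose(rows.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError(f"CPT rows for {self.node} do not sum to 1")
        if (self.values < -1e-15).any():
            raise ValueError(f"negative probability in CPT for {self.node}")


@dataclass
class BayesNet:
    """A DAG plus one CPT per node and the per-node variable specs."""

    dag: DAG
    cpts: dict[str, CPT]
    specs: dict[str, VariableSpec]
    uniform_rows: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for node in self.dag.nodes:
            if node not in self.cpts:
                raise ValueError(f"missing CPT for node {node}")
            if self.cpts[node].parents != self.dag.parents(node):
                raise ValueError(f"CPT parents for {node} do not match DAG")
            self.cpts[node].validate()

    def card(self, node: str) -> int:
        return self.specs[node].n_states

    def states(self, node: str) -> tuple[str, ...]:
        return self.specs[node].states

    def state_index(self, node: str, state: str) -> int:
        return self.specs[node].state_index(state)

    # -- serialization ---------------------------------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "nodes": [
                {
                    "name": n,
                    "states": list(self.specs[n].states),
                    "family": self.specs[n].family,
                }
                for n in self.dag.nodes
            ],
            "edges": sorted(list(e) for e in self.dag.edges),
            "cpts": {
                n: {
                    "parents": list(self.cpts[n].parents),
                    "values": self.cpts[n].values.tolist(),
                }
                for n in self.dag.nodes
            },
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "BayesNet":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        payload = json.loads(text)
        specs = {
            d["name"]: VariableSpec(d["name"], tuple(d["states"]), family=d.get("family"))
            for d in payload["nodes"]
        }
        dag = DAG([d["name"] for d in payload["nodes"]], [tuple(e) for e in payload["edges"]])
        cpts = {
            n: CPT(n, tuple(c["parents"]), np.asarray(c["values"], dtype=float))
            for n, c in payload["cpts"].items()
        }
        return cls(dag, cpts, specs)


# ---------------------------------------------------------------------------
# BIC scoring
# ---------------------------------------------------------------------------

class _LocalScores:
    """Cached per-node BIC components over an integer-coded cohort.

    Columns are re-coded to their observed states so that the dimension
    penalty reflects the cohort's effective cardinalities.
    """

    def __init__(self, cohort: Cohort):
        raw = cohort.codes()
        self.columns = cohort.variables
        self.index = {v: i for i, v in enumerate(self.columns)}
        self.n = raw.shape[0]
        self.log_n = math.log(self.n)
        cols = []
        cards = []
        for j in range(raw.shape[1]):
            observed = np.unique(raw[:, j])
            remap = np.full(observed.max() + 1, -1, dtype=np.int64)
            remap[observed] = np.arange(len(observed))
            cols.append(remap[raw[:, j]])
            cards.append(len(observed))
        self.codes = np.column_stack(cols)
        self.cards = np.array(cards)
        self._cache: dict[tuple[str, tuple[str, ...]], float] = {}

    def effective_card(self, node: str) -> int:
        return int(self.cards[self.index[node]])

    def __call__(self, node: str, parents: tuple[str, ...]) -> float:
        key = (node, tuple(sorted(parents)))
        if key in self._cache:
            return self._cache[key]
        j = self.index[node]
        r = self.cards[j]
        child = self.codes[:, j]
        q = 1
        cfg = np.zeros(self.n, dtype=np.int64)
        for p in key[1]:
            pj = self.index[p]
            cfg = cfg * self.cards[pj] + self.codes[:, pj]
            q *= int(self.cards[pj])
        counts = np.bincount(cfg * r + child, minlength=q * r).reshape(q, r)
        row_tot = counts.sum(axis=1, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            ll = counts * np.log(np.where(counts > 0, counts, 1) / np.where(row_tot > 0, row_tot, 1))
        score = float(ll.sum()) - 0.5 * (r - 1) * q * self.log_n
        self._cache[key] = score
        return score


def bic_score(dag: DAG, cohort: Cohort, scores: _LocalScores | None = None) -> float:
    """Decomposable BIC of a structure on a cohort (higher is better)."""
    scores = scores or _LocalScores(cohort)
    return sum(scores(node, dag.parents(node)) for node in dag.nodes)


# ---------------------------------------------------------------------------
# Structure search
# ---------------------------------------------------------------------------

def _hill_climb(
    start: DAG,
    scores: _LocalScores,
    blacklist: EdgeBlacklist,
    tol: float = 1e-9,
) -> tuple[DAG, float]:
    nodes = start.nodes
    dag = start
    total = sum(scores(n, dag.parents(n)) for n in nodes)
    while True:
        best: tuple[float, int, str, str] | None = None  # (delta, type, parent, child)
        for p in nodes:
            for c in nodes:
                if p == c:
                    continue
                if dag.has_edge(p, c):
                    # delete
                    delta = scores(c, _drop(dag.parents(c), p)) - scores(c, dag.parents(c))
                    best = _pick(best, (delta, 1, p, c))
                    # reverse
                    if (c, p) not in blacklist and not dag.without_edge(p, c).would_cycle(c, p):
                        delta_rev = (
                            scores(c, _drop(dag.parents(c), p))
                            - scores(c, dag.parents(c))
                            + scores(p, _add(dag.parents(p), c))
                            - scores(p, dag.parents(p))
                        )
                        best = _pick(best, (delta_rev, 2, p, c))
                else:
                    if (p, c) in blacklist or dag.would_cycle(p, c):
                        continue
                    delta = scores(c, _add(dag.parents(c), p)) - scores(c, dag.parents(c))
                    best = _pick(best, (delta, 0, p, c))
        if best is None or best[0] <= tol:
            return dag, total
        delta, kind, p, c = best
        if kind == 0:
            dag = dag.with_edge(p, c)
        elif kind == 1:
            dag = dag.without_edge(p, c)
        else:
            dag = dag.without_edge(p, c).with_edge(c, p)
        total += delta


def _drop(parents: tuple[str, ...], p: str) -> tuple[str, ...]:
    return tuple(x for x in parents if x != p)


def _add(parents: tuple[str, ...], p: str) -> tuple[str, ...]:
    return tuple(sorted(parents + (p,)))


def _pick(best, cand):
    """Keep the higher-delta move; ties broken by (move kind, parent, child)."""
    if cand[0] != cand[0]:  # NaN guard
        return best
    if best is None:
        return cand
    if cand[0] > best[0] + 1e-12:
        return cand
    if abs(cand[0] - best[0]) <= 1e-12 and (cand[1], cand[2], cand[3]) < (best[1], best[2], best[3]):
        return cand
    return best


def learn_structure(
    cohort: Cohort,
    blacklist: EdgeBlacklist | None = None,
    seed: int = 0,
    restarts: int = 10,
) -> DAG:
    """Greedy BIC hill-climbing with random restarts.

    Single-edge add/delete/reverse moves; never creates cycles or
    blacklisted edges; accepts the best strictly improving move with
    deterministic tie-breaking; the best local optimum over ``restarts``
    seeded random-restart runs is returned.  Restart k > 0 starts from an
    empty graph perturbed by two random feasible edge additions.
    """
    variables = cohort.variables
    if len(variables) >= 20:
        raise DAGError("exact-network budget: fewer than 20 variables required")
    blacklist = blacklist or EdgeBlacklist()
    blacklist.validate(variables)
    scores = _LocalScores(cohort)
    rng = np.random.default_rng(seed)
    best_dag, best_score = None, -math.inf
    for k in range(max(1, restarts)):
        start = DAG(variables)
        if k > 0:
            for _ in range(2):
                pairs = [
                    (p, c)
                    for p in variables
                    for c in variables
                    if p != c
                    and not start.has_edge(p, c)
                    and (p, c) not in blacklist
                    and not start.would_cycle(p, c)
                ]
                if not pairs:
                    break
                p, c = pairs[int(rng.integers(len(pairs)))]
                start = start.with_edge(p, c)
        dag, score = _hill_climb(start, scores, blacklist)
        if score > best_score + 1e-12:
            best_dag, best_score = dag, score
    assert best_dag is not None
    return best_dag


# ---------------------------------------------------------------------------
# Parameter estimation
# ---------------------------------------------------------------------------

class ParamFitter:
    """Reusable parameter estimator for a fixed DAG and cohort.

    Precomputes per-node flat (parent-config, state) indices so that
    bootstrap replicates (row resamples) refit in O(n) per node.
    """

    def __init__(self, dag: DAG, cohort: Cohort):
        self.dag = dag
        self.cohort = cohort
        codes = cohort.codes()
        index = {v: i for i, v in enumerate(cohort.variables)}
        self.cards = {v: cohort.spec(v).n_states for v in cohort.variables}
        self._flat: dict[str, np.ndarray] = {}
        self._shape: dict[str, tuple[int, ...]] = {}
        for node in dag.nodes:
            parents = dag.parents(node)
            r = self.cards[node]
            cfg = np.zeros(cohort.n, dtype=np.int64)
            q = 1
            for p in parents:
                cfg = cfg * self.cards[p] + codes[:, index[p]]
                q *= self.cards[p]
            self._flat[node] = cfg * r + codes[:, index[node]]
            self._shape[node] = tuple(self.cards[p] for p in parents) + (r,)

    def fit(
        self,
        rows: np.ndarray | None = None,
        method: str = "bayes",
        alpha: float = 1.0,
    ) -> BayesNet:
        if method not in {"mle", "bayes"}:
            raise ValueError("method must be 'mle' or 'bayes'")
        if method == "bayes" and alpha <= 0:
            raise ValueError("alpha must be positive for Bayesian estimation")
        cpts: dict[str, CPT] = {}
        uniform_rows: dict[str, int] = {}
        for node in self.dag.nodes:
            shape = self._shape[node]
            r = shape[-1]
            size = int(np.prod(shape))
            flat = self._flat[node] if rows is None else self._flat[node][rows]
            counts = np.bincount(flat, minlength=size).reshape(-1, r).astype(float)
            if method == "bayes":
                counts += alpha
                probs = counts / counts.sum(axis=1, keepdims=True)
            else:
                tot = counts.sum(axis=1, keepdims=True)
                empty = tot[:, 0] == 0
                if empty.any():
                    uniform_rows[node] = int(empty.sum())
                    counts[empty] = 1.0
                    tot = counts.sum(axis=1, keepdims=True)
                probs = counts / tot
            cpts[node] = CPT(node, self.dag.parents(node), probs.reshape(shape))
        specs = {n: self.cohort.spec(n) for n in self.dag.nodes}
        return BayesNet(self.dag, cpts, specs, uniform_rows=uniform_rows)


def fit_parameters(
    dag: DAG, cohort: Cohort, method: str = "bayes", alpha: float = 1.0
) -> BayesNet:
    """Estimate CPTs on a fixed structure.

    ``mle``: cell probability = count / row total, with a uniform
    fallback for parent configurations never observed (recorded in the
    returned net's ``uniform_rows``).  ``bayes``: symmetric-Dirichlet
    smoothing, (count + alpha) / (row total + alpha * r).
    """
    return ParamFitter(dag, cohort).fit(method=method, alpha=alpha)
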