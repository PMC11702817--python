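"""Categorical feature selection for the network's variable set.

Candidate predictors are ranked by Pearson chi-square association and
plug-in mutual information with the outcome, pruned for redundancy with
a Jaccard similarity matrix (preferring variables with standard clinical
definitions), and the final set is fixed by a k-of-m logistic-regression
combination search plus forced clinical includes.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score

from .cohort import UNKNOWN, Cohort

__all__ = [
    "FeatureRanking",
    "CombinationResult",
    "rank_features",
    "prune_redundant",
    "derive_threshold",
    "search_combinations",
    "assemble_pgm_features",
]

#: Exact networks are limited to fewer than this many variables.
MAX_PGM_VARIABLES = 20


class FeatureSelectionError(ValueError):
    pass


@dataclass
class FeatureRanking:
    """Per-variable association metrics and a combined rank (1 = best)."""

    table: pd.DataFrame  # index: variable; chi2_stat, chi2_p, mi, degenerate, combined_rank

    def top(self, m: int) -> list[str]:
        return list(self.table.sort_values("combined_rank").index[:m])

    def __getitem__(self, variable: str) -> pd.Series:
        return self.table.loc[variable]


@dataclass(frozen=True)
class CombinationResult:
    feature_set: tuple[str, ...]
    auc: float
    n_evaluated: int
    flagged: tuple[str, ...] = ()  # subsets that needed a penalised fallback fit


def _pairwise_complete(cohort: Cohort, var: str) -> tuple[np.ndarray, np.ndarray]:
    x = cohort.records[var].to_numpy()
    y = cohort.records[cohort.outcome].to_numpy()
    keep = x != UNKNOWN
    return x[keep], y[keep]


def _entropy_bits(counts: np.ndarray) -> float:
    p = counts / counts.sum()
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def rank_features(cohort: Cohort, variables: Sequence[str] | None = None) -> FeatureRanking:
    """Chi-square statistic/p-value and plug-in mutual information (bits)
    of every predictor with the outcome; unknowns excluded pairwise.

    The combined rank is the rank-sum of the two per-metric ranks, ties
    broken lexicographically by variable name.  A variable with a single
    observed state is flagged degenerate with both metrics zero.
    """
    variables = list(variables) if variables is not None else list(cohort.predictors)
    rows = {}
    for var in variables:
        x, y = _pairwise_complete(cohort, var)
        table = pd.crosstab(pd.Series(x), pd.Series(y)).to_numpy()
        if table.shape[0] < 2 or table.shape[1] < 2:
            rows[var] = {"chi2_stat": 0.0, "chi2_p": 1.0, "mi": 0.0, "degenerate": True}
            continue
        chi2, p, _, _ = chi2_contingency(table, correction=False)
        n = table.sum()
        hx = _entropy_bits(table.sum(axis=1))
        hy = _entropy_bits(table.sum(axis=0))
        hxy = _entropy_bits(table.reshape(-1))
        mi = max(hx + hy - hxy, 0.0)
        rows[var] = {"chi2_stat": float(chi2), "chi2_p": float(p), "mi": mi, "degenerate": False}
    df = pd.DataFrame.from_dict(rows, orient="index")
    order = pd.DataFrame(
        {
            "chi2_rank": df["chi2_stat"].rank(ascending=False, method="min"),
            "mi_rank": df["mi"].rank(ascending=False, method="min"),
        }
    )
    rank_sum = order["chi2_rank"] + order["mi_rank"]
    final = (
        pd.DataFrame({"rank_sum": rank_sum, "name": df.index})
        .sort_values(["rank_sum", "name"])
        .assign(combined_rank=lambda d: np.arange(1, len(d) + 1))
    )
    df["combined_rank"] = final.set_index("name")["combined_rank"]
    return FeatureRanking(df)


def jaccard(a: np.ndarray, b: np.ndarray) -> float:
    """|A n B| / |A u B| over "present" sets; 0 when both sets are empty."""
    inter = int(np.sum(a & b))
    union = int(np.sum(a | b))
    return inter / union if union else 0.0


def prune_redundant(
    ranking: FeatureRanking, cohort: Cohort, threshold: float = 0.8
) -> list[str]:
    """Drop the worse-ranked member of every near-duplicate pair.

    For each pair with Jaccard similarity >= threshold the variable with
    the worse clinical rank (or, when unranked, worse combined rank) is
    dropped.  Variables are considered in a deterministic preference
    order, so the result does not depend on input ordering.
    """
    if not 0 < threshold <= 1:
        raise FeatureSelectionError("threshold must lie in (0, 1]")
    variables = list(ranking.table.index)

    def priority(var: str) -> tuple:
        spec = cohort.spec(var)
        cr = spec.clinical_rank if spec.clinical_rank is not None else np.inf
        return (cr, ranking.table.loc[var, "combined_rank"], var)

    present = {
        var: (cohort.records[var].to_numpy() == "present") for var in variables
    }
    kept: list[str] = []
    for var in sorted(variables, key=priority):
        if all(jaccard(present[var], present[k]) < threshold for k in kept):
            kept.append(var)
    return sorted(kept, key=variables.index)


def derive_threshold(values: Sequence[float], outcome: Sequence[str]) -> float:
    """Empirical cutpoint for a continuous variable by ROC methodology.

    Returns the observed value c maximising Youden's J for the rule
    "positive iff value >= c"; ties break toward the smaller cutpoint.
    """
    values = np.asarray(values, dtype=float)
    y = np.asarray([1 if o == "present" else 0 for o in outcome])
    if len(np.unique(values)) < 2:
        raise FeatureSelectionError("need at least two distinct values")
    if y.min() == y.max():
        raise FeatureSelectionError("both outcome classes must be present")
    n_pos, n_neg = y.sum(), (1 - y).sum()
    best_c, best_j = None, -np.inf
    for c in np.unique(values):
        pred = values >= c
        sens = np.sum(pred & (y == 1)) / n_pos
        spec = np.sum(~pred & (y == 0)) / n_neg
        j = sens + spec - 1
        if j > best_j + 1e-12:
            best_c, best_j = c, j
    return float(best_c)


def _design(cohort: Cohort, features: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    """Binary design matrix (present=1, absent/unknown=0) and outcome labels."""
    X = np.column_stack(
        [(cohort.records[f].to_numpy() == "present").astype(float) for f in features]
    )
    y = (cohort.records[cohort.outcome].to_numpy() == "present").astype(int)
    return X, y


def _fit_subset_auc(X: np.ndarray, y: np.ndarray) -> tuple[float, bool]:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = LogisticRegression(penalty=None, max_iter=200)
        model.fit(X, y)
        flagged = model.n_iter_[0] >= 200  # non-convergence suggests separation
        if flagged:
            model = LogisticRegression(penalty="l2", C=1.0, max_iter=500)
            model.fit(X, y)
    return float(roc_auc_score(y, model.decision_function(X))), flagged


def search_combinations(
    cohort: Cohort,
    top_m_features: Sequence[str],
    k: int,
    mode: str = "exhaustive",
    budget: int = 200_000,
    n_subsets: int = 1000,
    seed: int = 0,
) -> CombinationResult:
    """Best k-of-m feature subset by in-sample logistic-regression AUC.

    ``exhaustive`` fits every C(m, k) subset and refuses (reporting the
    exact count) when that exceeds ``budget``; ``sampled`` fits
    ``n_subsets`` seeded random subsets; ``greedy`` forward-selects to
    size k.  A subset whose unpenalised fit fails to converge (perfect
    separation) falls back to an L2-penalised fit and is flagged.
    """
    features = list(top_m_features)
    m = len(features)
    if k > m:
        raise FeatureSelectionError(f"k={k} exceeds m={m}")
    X_all, y = _design(cohort, features)
    flagged: list[str] = []

    def evaluate(subset: tuple[int, ...]) -> float:
        auc, flag = _fit_subset_auc(X_all[:, subset], y)
        if flag:
            flagged.append(",".join(features[i] for i in subset))
        return auc

    if mode == "exhaustive":
        total = comb(m, k)
        if total > budget:
            raise FeatureSelectionError(
                f"exhaustive search over C({m},{k}) = {total} subsets exceeds the "
                f"budget of {budget}; use mode='sampled' or mode='greedy'"
            )
        candidates = list(combinations(range(m), k))
    elif mode == "sampled":
        rng = np.random.default_rng(seed)
        seen = set()
        while len(seen) < min(n_subsets, comb(m, k)):
            seen.add(tuple(sorted(rng.choice(m, size=k, replace=False))))
        candidates = sorted(seen)
    elif mode == "greedy":
        chosen: list[int] = []
        remaining = list(range(m))
        while len(chosen) < k:
            scored = [
                (evaluate(tuple(sorted(chosen + [i]))), -i) for i in remaining
            ]
            best_i = -max(scored)[1]
            chosen.append(best_i)
            remaining.remove(best_i)
        subset = tuple(sorted(chosen))
        auc, _ = _fit_subset_auc(X_all[:, subset], y)
        return CombinationResult(
            tuple(features[i] for i in subset),
            auc,
            n_evaluated=sum(m - i for i in range(k)),
            flagged=tuple(flagged),
        )
    else:
        raise FeatureSelectionError(f"unknown mode {mode!r}")

    best_auc, best_subset = -np.inf, None
    for subset in candidates:
        auc = evaluate(subset)
        if auc > best_auc + 1e-12:
            best_auc, best_subset = auc, subset
    assert best_subset is not None
    return CombinationResult(
        tuple(features[i] for i in best_subset),
        best_auc,
        n_evaluated=len(candidates),
        flagged=tuple(flagged),
    )


def assemble_pgm_features(
    cohort: Cohort,
    best_set: Sequence[str],
    forced_includes: Sequence[str] = (),
    p_threshold: float = 0.05,
) -> list[str]:
    """Final network feature list: the significant terms (two-sided Wald
    p < 0.05) of the best logistic model, union the forced clinical
    includes, de-duplicated with stable order.  Exact networks require
    fewer than 20 variables."""
    import statsmodels.api as sm

    X, y = _design(cohort, list(best_set))
    model = sm.Logit(y, sm.add_constant(X, has_constant="add"))
    try:
        fit = model.fit(disp=0)
        pvalues = fit.pvalues[1:]
    except Exception:  # perfect separation or singular design
        warnings.warn("logistic fit failed; keeping the full best set")
        pvalues = np.zeros(len(best_set))
    significant = [f for f, p in zip(best_set, pvalues) if p < p_threshold]
    final = list(dict.fromkeys([*significant, *forced_includes]))
    if len(final) + 1 >= MAX_PGM_VARIABLES:  # +1 for the outcome node
        raise FeatureSelectionError(
            f"{len(final)} features plus the outcome reach the exact-network "
            f"limit of {MAX_PGM_VARIABLES} variables"
        )
    return final
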