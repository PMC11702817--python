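"""Model evaluation: stratified splits, cross-validation, AUC with
bootstrap confidence intervals, model comparison, and rare-scenario
("N of 1") subset performance.

AUC follows the Mann-Whitney convention (ties count one half); the
optimal operating threshold maximises Youden's J.  Confidence intervals
use class-stratified bootstrap resampling of (score, label) pairs, and
two models are compared by the paired-bootstrap distribution of their
AUC difference.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold

from .bayesnet import EdgeBlacklist, blacklist_from_families, fit_parameters, learn_structure
from .cohort import Cohort
from .inference import predict_batch

__all__ = [
    "SplitSpec",
    "EvalReport",
    "split",
    "cross_validate",
    "auc_with_ci",
    "compare_auc",
    "unique_scenarios",
    "pgm_model_builder",
    "logistic_model_builder",
]


class EvaluationError(ValueError):
    pass


@dataclass(frozen=True)
class SplitSpec:
    derivation_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.derivation_fraction < 1:
            raise EvaluationError("derivation fraction must lie in (0, 1)")


@dataclass
class EvalReport:
    auc: float
    ci_low: float
    ci_high: float
    threshold: float
    n: int
    subset: str = "full"

    def as_dict(self) -> dict:
        return {
            "auc": self.auc,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "threshold": self.threshold,
            "n": self.n,
            "subset": self.subset,
        }


def _labels(cohort: Cohort) -> np.ndarray:
    return (cohort.records[cohort.outcome].to_numpy() == "present").astype(int)


def split(cohort: Cohort, spec: SplitSpec | None = None) -> tuple[Cohort, Cohort]:
    """Outcome-stratified derivation/validation split.

    The validation side takes round((1 - fraction) * n) records per
    outcome class; the result is an exact partition, deterministic given
    the seed.
    """
    spec = spec or SplitSpec()
    y = _labels(cohort)
    if y.min() == y.max():
        raise EvaluationError("both outcome classes must be present")
    rng = np.random.default_rng(spec.seed)
    val_mask = np.zeros(cohort.n, dtype=bool)
    for cls in (0, 1):
        idx = np.flatnonzero(y == cls)
        if len(idx) < 5:
            warnings.warn(f"outcome class {cls} has only {len(idx)} members")
        n_val = round((1 - spec.derivation_fraction) * len(idx))
        chosen = rng.permutation(idx)[:n_val]
        val_mask[chosen] = True
    return cohort.subset(~val_mask), cohort.subset(val_mask)


ModelBuilder = Callable[[Cohort, int], Callable[[Cohort], np.ndarray]]


def cross_validate(
    cohort: Cohort,
    folds: int = 5,
    model_builder: ModelBuilder | None = None,
    seed: int = 0,
    max_refolds: int = 10,
) -> dict:
    """Class-stratified k-fold cross-validation.

    ``model_builder(train_cohort, seed)`` returns a scorer mapping a
    held-out cohort to event probabilities.  Returns per-fold AUCs and
    their mean.  A fold lacking both classes triggers a reshuffle with a
    new seed (logged via warning).
    """
    if folds < 2:
        raise EvaluationError("need at least 2 folds")
    model_builder = model_builder or logistic_model_builder()
    y = _labels(cohort)
    for attempt in range(max_refolds):
        kf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed + attempt)
        splits = list(kf.split(np.zeros(len(y)), y))
        if all(len(np.unique(y[te])) == 2 for _, te in splits):
            if attempt:
                warnings.warn(f"refolded {attempt} time(s) to get both classes per fold")
            break
    else:
        raise EvaluationError("could not stratify folds with both classes")
    aucs = []
    for i, (tr, te) in enumerate(splits):
        scorer = model_builder(cohort.subset(np.isin(np.arange(len(y)), tr)), seed + i)
        scores = scorer(cohort.subset(np.isin(np.arange(len(y)), te)))
        aucs.append(float(roc_auc_score(y[te], scores)))
    return {"fold_aucs": aucs, "mean_auc": float(np.mean(aucs))}


def _youden_threshold(scores: np.ndarray, labels: np.ndarray) -> float:
    fpr, tpr, thresholds = roc_curve(labels, scores)
    j = tpr - fpr
    best = np.flatnonzero(j >= j.max() - 1e-12)
    return float(thresholds[best[-1]])  # last index = smallest threshold


def auc_with_ci(
    scores: Sequence[float],
    labels: Sequence[int],
    b: int = 1000,
    seed: int = 0,
    subset: str = "full",
) -> EvalReport:
    """AUC (Mann-Whitney, ties half) with a class-stratified percentile
    bootstrap 95% CI and the Youden-optimal threshold."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if b < 2:
        raise EvaluationError("b must be at least 2")
    if labels.min() == labels.max():
        raise EvaluationError("both outcome classes must be present")
    auc = float(roc_auc_score(labels, scores))
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == 0)
    rng = np.random.default_rng(seed)
    reps = np.empty(b)
    for i in range(b):
        p = pos[rng.integers(0, len(pos), len(pos))]
        n = neg[rng.integers(0, len(neg), len(neg))]
        idx = np.concatenate([p, n])
        reps[i] = roc_auc_score(labels[idx], scores[idx])
    return EvalReport(
        auc=auc,
        ci_low=float(np.percentile(reps, 2.5)),
        ci_high=float(np.percentile(reps, 97.5)),
        threshold=_youden_threshold(scores, labels),
        n=len(labels),
        subset=subset,
    )


def compare_auc(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    labels: Sequence[int],
    b: int = 1000,
    seed: int = 0,
) -> float:
    """Two-sided p-value for AUC(a) = AUC(b) by paired bootstrap.

    Both models must score the same records; each replicate resamples
    record indices (class-stratified) and recomputes the AUC difference.
    The p-value is twice the fraction of replicates whose difference
    crosses zero relative to the observed sign, capped at 1.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores_a.shape != scores_b.shape or scores_a.shape != labels.shape:
        raise EvaluationError("both models must score the same records")
    delta = roc_auc_score(labels, scores_a) - roc_auc_score(labels, scores_b)
    if np.allclose(scores_a, scores_b):
        return 1.0
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == 0)
    rng = np.random.default_rng(seed)
    diffs = np.empty(b)
    for i in range(b):
        p = pos[rng.integers(0, len(pos), len(pos))]
        n = neg[rng.integers(0, len(neg), len(neg))]
        idx = np.concatenate([p, n])
        diffs[i] = roc_auc_score(labels[idx], scores_a[idx]) - roc_auc_score(
            labels[idx], scores_b[idx]
        )
    if delta >= 0:
        tail = float(np.mean(diffs <= 0))
    else:
        tail = float(np.mean(diffs >= 0))
    return min(1.0, 2 * tail)


# ---------------------------------------------------------------------------
# Rare ("N of 1") scenarios
# ---------------------------------------------------------------------------

@dataclass
class RareScenarioResult:
    mask: np.ndarray  # over validation rows
    n: int
    fraction_of_validation: float
    report: EvalReport | None
    reason: str | None = None


def unique_scenarios(
    cohort: Cohort,
    validation: Cohort,
    max_frequency: int = 1,
    scores: Sequence[float] | None = None,
    b: int = 1000,
    seed: int = 0,
) -> RareScenarioResult:
    """Validation rows whose full non-outcome state pattern occurs at most
    ``max_frequency`` times in the entire cohort (1 = "N of 1").

    Pattern frequencies are counted over the whole cohort, unknown states
    included.  When scores are supplied and both classes are present in
    the subset, an AUC report for the subset is attached.
    """
    pred_cols = [c for c in cohort.predictors if c in validation.variables]
    whole = cohort.records[pred_cols].apply(tuple, axis=1)
    freq = whole.value_counts()
    val_patterns = validation.records[pred_cols].apply(tuple, axis=1)
    mask = val_patterns.map(freq).fillna(0).to_numpy() <= max_frequency
    n = int(mask.sum())
    frac = n / validation.n
    report = None
    reason = None
    if n == 0:
        reason = "no rows at or below the frequency cut"
    elif scores is not None:
        labels = _labels(validation)[mask]
        if labels.min() == labels.max():
            reason = "subset lacks both outcome classes; AUC omitted"
        else:
            report = auc_with_ci(
                np.asarray(scores)[mask],
                labels,
                b=b,
                seed=seed,
                subset=f"pattern frequency <= {max_frequency}",
            )
    return RareScenarioResult(mask, n, frac, report, reason)


# ---------------------------------------------------------------------------
# Model builders
# ---------------------------------------------------------------------------

def pgm_model_builder(
    blacklist: EdgeBlacklist | None = None,
    restarts: int = 5,
    method: str = "bayes",
    alpha: float = 1.0,
    from_families: bool = True,
) -> ModelBuilder:
    """Builder learning a network (structure + parameters) on the training
    fold and scoring held-out records by exact per-record prediction."""

    def build(train: Cohort, seed: int) -> Callable[[Cohort], np.ndarray]:
        bl = blacklist
        if bl is None and from_families:
            bl = blacklist_from_families(train.specs)
        dag = learn_structure(train, blacklist=bl, seed=seed, restarts=restarts)
        net = fit_parameters(dag, train, method=method, alpha=alpha)
        return lambda test: predict_batch(net, test, train.outcome)

    return build


def logistic_model_builder(**kwargs) -> ModelBuilder:
    """Builder fitting an L2-regularised logistic model on present/absent
    indicator columns."""

    def build(train: Cohort, seed: int) -> Callable[[Cohort], np.ndarray]:
        feats = list(train.predictors)
        Xtr = np.column_stack(
            [(train.records[f].to_numpy() == "present").astype(float) for f in feats]
        )
        model = LogisticRegression(max_iter=500, **kwargs)
        model.fit(Xtr, _labels(train))

        def score(test: Cohort) -> np.ndarray:
            Xte = np.column_stack(
                [(test.records[f].to_numpy() == "present").astype(float) for f in feats]
            )
            return model.predict_proba(Xte)[:, 1]

        return score

    return build
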