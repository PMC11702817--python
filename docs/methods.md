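# Methods

## Problem and model

Fetal growth restriction (FGR, estimated fetal weight below the 10th
percentile) is a leading stillbirth risk factor, yet most growth-restricted
infants are healthy: the diagnosis alone is a poor risk stratifier. This
package implements a context-specific risk-estimation analysis for a
composite perinatal morbidity/mortality outcome (any of stillbirth,
neonatal death, mechanical ventilation, RDS, NEC, confirmed sepsis,
grade 3–4 IVH, seizures, or NICU stay > 7 days) in a nulliparous obstetric
cohort, using a discrete Bayesian network.

A Bayesian network here is a DAG over categorical clinical variables, each
node carrying a conditional probability table (CPT); the joint distribution
factorises as P(x) = ∏ᵢ P(xᵢ | pa(xᵢ)). Because the joint is explicit and
exact, any variable can be queried as the target given any partial evidence
("scenario"), which is what produces context-specific absolute risks (AR),
relative risks (RR = AR ratio), and interaction findings without refitting.

Missing data is modelled, not imputed: every variable carries a reserved
`unknown` state that behaves as an ordinary category in scoring, fitting and
inference. A record whose EFW is missing is *conditioned on* EFW = unknown;
training and prediction therefore agree on the meaning of missingness.

## Structure learning

Greedy hill-climbing over single-edge add/delete/reverse moves, scored by
BIC (natural logs): score(G) = log L̂ − (d/2)·ln N with d = Σᵢ (rᵢ−1)·qᵢ
(rᵢ states, qᵢ parent configurations). Ten seeded random restarts (two
random feasible edge additions each) guard against local optima; ties are
broken deterministically by (move kind, parent, child), so learning is
reproducible given the seed.

Two kinds of clinically motivated blacklists are honoured:

* **family blacklists** — both edge directions are forbidden between
  mutually exclusive one-hot siblings (the gestational-age categories and
  EFW-percentile categories), which otherwise would "predict" each other
  through the encoding alone;
* **terminal-outcome blacklist** — no edges out of the composite outcome.
  Besides its clinical reading, this matters statistically: an outcome
  oriented as a *parent* of fetal sex cannot express a sex-by-diabetes
  interaction in any CPT, whereas sex and diabetes as co-parents of the
  outcome can.

One numerical choice deserves note: a state that is declared but never
observed in a cohort (e.g. `unknown` for a fully observed variable)
contributes nothing to the likelihood but would inflate the BIC dimension
penalty roughly 1.5-fold per node. Structure scoring therefore uses
*effective* cardinalities — the states actually present in the data —
while parameter fitting and inference always span the full declared state
space. Zero counts contribute 0·ln 0 := 0.

## Parameter estimation

Default is Bayesian estimation with a symmetric Dirichlet prior,
p̂ = (count + α)/(rowtotal + α·r), α = 1. Maximum likelihood
(count/rowtotal) is available and is what the bootstrap machinery refits,
so that point estimates are the fitted model's MLEs; parent configurations
never observed fall back to a uniform row and are flagged on the returned
network. Note the smoothed estimator assigns small mass to `unknown`
states even for fully observed variables; with α = 1 this is ≤ 1/(n_row+r)
per row and immaterial at the row supports used here.

## Inference

Exact conditional queries run by variable elimination with a min-fill
ordering; a full-joint enumeration oracle (refusing beyond 10⁷
configurations) provides the independent cross-check used throughout the
tests (equivalence to 1e-10). Evidence with zero probability raises an
explicit inconsistency error rather than returning a uniform or NaN
distribution — silently continuing would corrupt downstream RR estimates.
Per-record prediction (every non-target node observed) reduces to
normalising the joint factorisation over the target's states and is
vectorised across records.

## Risk estimation and the bootstrap

AR(scenario) = P(outcome = present | evidence); RR compares two ARs, with
the model's own background marginal (empty evidence) as the default
reference — all reported risks are model-based quantities, with matching
derivation-record counts (`n_matching`) reported alongside, including
legitimate zeros for scenarios no participant exhibits. Confidence
intervals are percentile bootstrap: resample N records with replacement,
refit parameters on the fixed learned structure, recompute the query;
2.5th/97.5th percentiles over B = 1000 replicates (B = 200 in the scaled
test-suite runs). Structure is *not* relearned per replicate (a flagged
option exists): the reported point estimates are tied to one network, and
interval semantics then quantify parameter, not search, uncertainty.
Replicates in which a query's evidence mass is zero are dropped and
counted. Since point estimates are MLEs rather than bootstrap means, they
need not sit at the interval's centre.

Interaction (effect-modification) scanning estimates, within each stratum
of a context variable, the RR of the outcome for the effect variable
versus its reference level, with bootstrap replicates shared across strata.
A finding is flagged when two strata have non-overlapping 95% intervals —
`reversal` when the direction of effect (sign of RR − 1) also flips,
`magnitude` otherwise. No multiplicity correction is applied; findings are
screening signals, not confirmatory tests.

## Evaluation

Outcome-stratified 80/20 derivation/validation split (per-class rounding;
with 9,558 records and 783 events this yields a 1,912-record validation
side). Stratified 5-fold cross-validation within the derivation cohort.
Discrimination is AUC under the Mann–Whitney convention (ties count ½),
with class-stratified bootstrap percentile CIs and a Youden-maximising
operating threshold; two models scored on the same records are compared by
the paired-bootstrap distribution of ΔAUC (two-sided). Rare-scenario
("N of 1") analysis counts each validation record's full non-outcome state
pattern over the *entire* cohort and evaluates AUC on the subset at or
below a frequency cut (1, 5, 10); the subsets are nested by construction.

## Feature selection

Candidates are one-hot encoded binaries. Association with the outcome is
ranked by Pearson chi-square and plug-in discrete mutual information
(bits), combined by rank-sum with lexicographic tie-breaks; unknowns are
excluded pairwise. "Mutual information criterion" is read as plain
discrete MI — every predictor is categorical after encoding, so the
maximal-information-coefficient reading would reduce to it anyway.
Redundancy is pruned with a Jaccard similarity matrix over "present" sets
(threshold 0.8 by default; 0/0 defined as 0), preferring variables with
standard clinical definitions (`clinical_rank`) and falling back to the
combined rank — the pass order is deterministic, so the result does not
depend on column order. The final set comes from a k-of-m logistic
combination search (exhaustive mode refuses, with the exact count, when
C(m,k) exceeds the budget — C(30,12) = 86,493,225 — with seeded-sample and
greedy alternatives), keeping the best subset's Wald-significant terms
(two-sided p < 0.05) plus forced clinical includes, under the < 20-variable
exact-network budget. Subset AUC is computed in-sample on the derivation
cohort. ROC-derived cutpoints for continuous variables maximise Youden's J
over observed values, ties toward the smaller cutpoint.

## Synthetic cohort generator

The generator is the study's data source: a fully parameterised truth
network over 12 categorical variables (preexisting diabetes, progesterone
use, fetal sex, congenital anomaly, visit-2 BP > 140/90, PPROM, HDP,
EFW-percentile category, gestational-age category, urgent cesarean,
5-minute Apgar < 7, composite morbidity) whose exact marginals match the
published cohort characteristics — morbidity 8.2%, diabetes 1.6%,
progesterone 2.6%, female 50.9%, anomaly 5.9%, HDP 10.0%, urgent cesarean
9.1%, Apgar < 7 4.0%, EFW <3rd/3–9th/>90th = 1.0/4.3/7.3%, early/late
preterm = 2.8/5.8% — verified by exact inference to within 0.1 percentage
point at construction. Dependencies follow the published network's shape:
diabetes → {EFW, HDP, outcome}; HDP → {GA, urgent cesarean};
progesterone/PPROM → GA; GA → {outcome, Apgar}; anomaly → outcome;
sex → outcome.

Conditional rates are multiplicative-risk rows whose baselines are solved
(linear where uncapped, bisection against the exact parent joint where a
0.95 risk cap binds) so the marginal targets hold exactly. The planted
interaction multiplies outcome risk by 0.6 for a female fetus without
diabetes and by 2.5 (male) / 4.0 (female) with diabetes — a within-stratum
female:male RR of ≈ 1.6 with diabetes versus ≈ 0.6 without. These
magnitudes are choices, not calibrations to the real study's printed RRs
(which come from restricted data); they were set strong enough to be
learnable at a 1.6% diabetes prevalence. The no-interaction control sets
the diabetic female multiplier to 2.5 × 0.6 so the sex effect is constant
across strata (up to small cap distortion in the rare diabetic stratum).
Missingness is injected MCAR (EFW 6.4%, visit-2 BP 4.9%; the real
mechanism is uncharacterised) and never touches the outcome. One-hot
families are sampled as single categorical nodes and expanded afterwards,
guaranteeing mutual exclusivity.

What the generator does *not* emulate: real nuMoM2b correlation structure
beyond the planted edges, continuous biometry, informative missingness,
measurement error, or site effects. Passing tests therefore demonstrate
that the machinery recovers known structure under the published marginal
conditions — not that the real-data point estimates (validation AUC 0.83,
scenario RRs 0.9–9.8) are reproduced, which requires the access-restricted
cohort.

## Problem sizes used in the checked runs

The analysis scripts simulate n = 50,000 pregnancies: several planted
effects — the sex effect and its diabetes-specific reversal in particular —
sit right at the BIC detection boundary at the real study's n ≈ 9.6k
(diabetes prevalence 1.6% leaves ~150 diabetic pregnancies), and the
statistical suites are specified at n = 50,000. At n = 20,000 BIC
(correctly) prices the sex term out of the outcome CPT; the package makes
that trade-off visible rather than hiding it. Parameter-recovery checks
run at n = 200,000; bootstrap coverage uses 200 cohorts of n = 5,000 with
B = 200; the interaction power/specificity check uses 50 seeds at
n = 50,000.

## Known limitations

* Per-row CPT recovery is limited by row support: parent configurations
  combining diabetes (1.6%), early preterm birth and anomaly have
  single-digit expected counts even at n = 200,000, so their conditional
  rows cannot be pinned to TV ≤ 0.01 by any estimator; recovery statements
  are meaningful for well-supported rows and in probability-weighted form.
* Percentile-bootstrap intervals for queries conditioned on sparse
  evidence (e.g. within the diabetic stratum at small n) can undercover,
  because MLE refits on near-empty cells underestimate their own
  variability; the background-risk interval is well calibrated (measured
  ≈ 95% coverage).
* The hill climber explores single-edge moves only (no tabu list); random
  restarts are the defence against local optima.
* Associational, not causal: queries condition, they do not intervene.
  Progesterone use in particular proxies clinical concern in the real
  cohort, and no do-calculus semantics are claimed.
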