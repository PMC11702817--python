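"""Cohort data model and clinical encodings.

A cohort is a table of categorical clinical variables, one row per
pregnancy, with a designated binary composite-morbidity outcome.  Missing
data is represented by the reserved state ``"unknown"``, which downstream
modules treat as an ordinary category rather than imputing or dropping it.

This module owns the clinical encoding rules: the nine-component composite
perinatal morbidity outcome, the estimated-fetal-weight (EFW) percentile
categories, gestational-age-at-birth categories, the dichotomised
hypertensive-disorders-of-pregnancy (HDP) definition, one-hot expansion of
mutually exclusive category families, the cohort exclusion filters, and
"% (n)" summary tables.
"""
from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

UNKNOWN = "unknown"
BINARY_STATES = ("absent", "present", UNKNOWN)

#: Components of the composite perinatal morbidity/mortality outcome.
OUTCOME_COMPONENTS = (
    "stillbirth",
    "neonatal_death",
    "mechanical_ventilation",
    "rds",
    "nec",
    "confirmed_sepsis",
    "ivh_grade34",
    "seizures",
    "nicu_gt7d",
)

#: HDP sub-types that qualify for the dichotomised HDP definition:
#: eclampsia, preeclampsia with severe features, or gestational
#: hypertension with onset prior to labor.
HDP_QUALIFYING = frozenset(
    {"eclampsia", "preeclampsia_severe", "gestational_htn_prelabor"}
)
HDP_LABELS = frozenset(
    {
        "none",
        "chronic_htn",
        "gestational_htn_prelabor",
        "gestational_htn_intrapartum",
        "preeclampsia_mild",
        "preeclampsia_severe",
        "superimposed_preeclampsia",
        "hellp",
        "eclampsia",
    }
)

EFW_STATES = ("lt3", "p3to9", "p10to90", "gt90", UNKNOWN)
GA_STATES = ("early_ptb", "late_ptb", "term", UNKNOWN)


class CohortError(ValueError):
    """Invalid cohort construction or encoding input."""


class EmptyCohortError(CohortError):
    """Raised when an operation would produce or receive an empty cohort."""


@dataclass(frozen=True)
class VariableSpec:
    """A categorical clinical variable.

    Parameters
    ----------
    name:
        Column identifier.
    states:
        Ordered category labels.  Must contain the reserved label
        ``"unknown"`` exactly once.
    family:
        Optional identifier grouping mutually exclusive one-hot siblings
        (e.g. the gestational-age categories).
    clinical_rank:
        Optional preference used during redundancy pruning; lower values
        are preferred (kept) when two variables are near-duplicates.
    """

    name: str
    states: tuple[str, ...] = BINARY_STATES
    family: str | None = None
    clinical_rank: int | None = None

    def __post_init__(self) -> None:
        states = tuple(self.states)
        object.__setattr__(self, "states", states)
        if len(set(states)) != len(states):
            raise CohortError(f"{self.name}: duplicate states {states}")
        if states.count(UNKNOWN) != 1:
            raise CohortError(f"{self.name}: states must contain 'unknown' exactly once")
        if len(states) < 2:
            raise CohortError(f"{self.name}: needs at least one observable state")

    @property
    def observed_states(self) -> tuple[str, ...]:
        return tuple(s for s in self.states if s != UNKNOWN)

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def is_binary(self) -> bool:
        return set(self.observed_states) == {"absent", "present"}

    def state_index(self, state: str) -> int:
        try:
            return self.states.index(state)
        except ValueError:
            raise CohortError(
                f"{self.name}: state {state!r} not in {self.states}"
            ) from None


def binary_spec(name: str, family: str | None = None, clinical_rank: int | None = None) -> VariableSpec:
    return VariableSpec(name, BINARY_STATES, family=family, clinical_rank=clinical_rank)


class Cohort:
    """A categorical record table with a designated binary outcome column."""

    def __init__(
        self,
        records: pd.DataFrame,
        outcome: str,
        specs: Mapping[str, VariableSpec],
        validate: bool = True,
    ):
        self.records = records.reset_index(drop=True)
        self.outcome = outcome
        self.specs = dict(specs)
        self._codes: np.ndarray | None = None
        if validate:
            self._validate()

    def _validate(self) -> None:
        if len(self.records) < 1:
            raise EmptyCohortError("cohort must contain at least one record")
        if self.outcome not in self.records.columns:
            raise CohortError(f"outcome column {self.outcome!r} missing")
        for col in self.records.columns:
            if col not in self.specs:
                raise CohortError(f"no VariableSpec for column {col!r}")
            bad = set(self.records[col].unique()) - set(self.specs[col].states)
            if bad:
                raise CohortError(f"{col}: values {bad} not in declared states")
        if (self.records[self.outcome] == UNKNOWN).any():
            raise CohortError("outcome column may not contain 'unknown'")

    # -- basic accessors -------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.records)

    @property
    def variables(self) -> tuple[str, ...]:
        return tuple(self.records.columns)

    @property
    def predictors(self) -> tuple[str, ...]:
        return tuple(c for c in self.records.columns if c != self.outcome)

    def spec(self, name: str) -> VariableSpec:
        return self.specs[name]

    def codes(self) -> np.ndarray:
        """Integer state codes, shape (n, p), aligned with each spec's state order."""
        if self._codes is None:
            cols = []
            for col in self.variables:
                cat = pd.Categorical(
                    self.records[col], categories=self.specs[col].states
                )
                c = np.asarray(cat.codes, dtype=np.int64)
                if (c < 0).any():
                    raise CohortError(f"{col}: value outside declared states")
                cols.append(c)
            self._codes = np.column_stack(cols)
        return self._codes

    def cards(self) -> np.ndarray:
        return np.array([self.specs[c].n_states for c in self.variables])

    def subset(self, mask: np.ndarray) -> "Cohort":
        return Cohort(self.records.loc[np.asarray(mask)], self.outcome, self.specs)

    def select(self, columns: Sequence[str]) -> "Cohort":
        cols = list(columns)
        if self.outcome not in cols:
            cols = cols + [self.outcome]
        return Cohort(self.records[cols], self.outcome, {c: self.specs[c] for c in cols})

    # -- persistence -----------------------------------------------------
    def to_csv(self, path: str | Path, schema_path: str | Path | None = None) -> None:
        path = Path(path)
        self.records.to_csv(path, index=False)
        schema_path = Path(schema_path) if schema_path else path.with_suffix(".schema.json")
        schema = {
            "outcome": self.outcome,
            "variables": {
                name: {
                    "states": list(s.states),
                    "family": s.family,
                    "clinical_rank": s.clinical_rank,
                }
                for name, s in self.specs.items()
            },
        }
        schema_path.write_text(json.dumps(schema, indent=2))

    @classmethod
    def from_csv(cls, path: str | Path, schema_path: str | Path | None = None) -> "Cohort":
        path = Path(path)
        schema_path = Path(schema_path) if schema_path else path.with_suffix(".schema.json")
        schema = json.loads(Path(schema_path).read_text())
        specs = {
            name: VariableSpec(
                name,
                tuple(v["states"]),
                family=v.get("family"),
                clinical_rank=v.get("clinical_rank"),
            )
            for name, v in schema["variables"].items()
        }
        records = pd.read_csv(path, dtype=str)
        return cls(records, schema["outcome"], specs)


# ---------------------------------------------------------------------------
# Raw records and exclusions
# ---------------------------------------------------------------------------

@dataclass
class RawRecord:
    """A pre-encoding participant record."""

    gestational_age_weeks: float
    outcome_available: bool = True
    outcome_components: dict[str, str] = field(default_factory=dict)
    efw_percentile: float | None = None
    hdp_subtype: str = "none"
    fields: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.gestational_age_weeks <= 0:
            raise CohortError("gestational age must be positive")
        if self.efw_percentile is not None and not (0 <= self.efw_percentile <= 100):
            raise CohortError("EFW percentile must lie in [0, 100]")


@dataclass(frozen=True)
class ExclusionReport:
    n_input: int
    n_missing_outcome: int
    n_early_delivery: int

    @property
    def n_analyzed(self) -> int:
        return self.n_input - self.n_missing_outcome - self.n_early_delivery


def apply_exclusions(
    raw_records: Sequence[RawRecord],
) -> tuple[list[RawRecord], ExclusionReport]:
    """Apply the two cohort exclusion criteria, in order.

    Records with missing birth/neonatal outcome data are removed first,
    then records delivered before 20 weeks' gestation; a record failing
    both is counted only at the first criterion.
    """
    records = list(raw_records)
    if not records:
        raise EmptyCohortError("no raw records supplied")
    survivors: list[RawRecord] = []
    n_missing = 0
    n_early = 0
    for rec in records:
        if not rec.outcome_available:
            n_missing += 1
        elif rec.gestational_age_weeks < 20:
            n_early += 1
        else:
            survivors.append(rec)
    return survivors, ExclusionReport(len(records), n_missing, n_early)


def derive_outcome(
    components: Mapping[str, str], missing_policy: str = "absent"
) -> str:
    """Composite outcome: present iff any of the nine components is present.

    A component flag that is missing from ``components`` is handled per
    ``missing_policy`` (default ``"absent"``, with a warning; ``"error"``
    raises instead).
    """
    present = False
    for comp in OUTCOME_COMPONENTS:
        if comp not in components:
            if missing_policy == "error":
                raise CohortError(f"missing outcome component {comp!r}")
            warnings.warn(
                f"outcome component {comp!r} missing; treated as absent",
                stacklevel=2,
            )
            continue
        if components[comp] == "present":
            present = True
    return "present" if present else "absent"


def categorize_efw(percentile: float | None) -> str:
    """EFW percentile category: <3rd, 3-9th, 10-90th, >90th, or unknown.

    Boundary convention: [3, 10) is "3-9th" and [10, 90] is "10-90th",
    so ">90th" means strictly above the 90th percentile and the four
    categories partition [0, 100].
    """
    if percentile is None or (isinstance(percentile, float) and math.isnan(percentile)):
        return UNKNOWN
    if not 0 <= percentile <= 100:
        raise CohortError(f"EFW percentile {percentile} outside [0, 100]")
    if percentile < 3:
        return "lt3"
    if percentile < 10:
        return "p3to9"
    if percentile <= 90:
        return "p10to90"
    return "gt90"


def categorize_ga(weeks: float) -> str:
    """Gestational age at birth: early preterm (<34w), late preterm
    ([34, 37)w, i.e. completed weeks 34-36), or term (>=37w).

    Deliveries before 20 weeks should already have been excluded.
    """
    if weeks is None or (isinstance(weeks, float) and math.isnan(weeks)):
        return UNKNOWN
    if weeks < 20:
        raise CohortError(f"gestational age {weeks} < 20 weeks (should be excluded)")
    if weeks < 34:
        return "early_ptb"
    if weeks < 37:
        return "late_ptb"
    return "term"


def dichotomize_hdp(subtype: str) -> str:
    """Dichotomised HDP: present iff eclampsia, preeclampsia with severe
    features, or pre-labor gestational hypertension."""
    if subtype not in HDP_LABELS:
        raise CohortError(
            f"unknown HDP subtype {subtype!r}; accepted: {sorted(HDP_LABELS)}"
        )
    return "present" if subtype in HDP_QUALIFYING else "absent"


# ---------------------------------------------------------------------------
# One-hot expansion
# ---------------------------------------------------------------------------

def one_hot(cohort: Cohort, variable: str) -> Cohort:
    """Expand a multi-state variable into mutually exclusive binary siblings.

    Each non-unknown state becomes a binary column named
    ``{variable}_{state}`` carrying the source variable's name as its
    family id.  A record whose source state is unknown has *all* siblings
    unknown; otherwise exactly one sibling is present.
    """
    spec = cohort.spec(variable)
    if len(spec.observed_states) < 3:
        warnings.warn(f"{variable} is binary; one-hot expansion is a no-op")
        return cohort
    df = cohort.records.copy()
    src = df[variable]
    specs = dict(cohort.specs)
    new_cols: dict[str, pd.Series] = {}
    for state in spec.observed_states:
        col = f"{variable}_{state}"
        vals = np.where(
            src == UNKNOWN, UNKNOWN, np.where(src == state, "present", "absent")
        )
        new_cols[col] = pd.Series(vals, index=df.index)
        specs[col] = VariableSpec(col, BINARY_STATES, family=variable)
    pos = list(df.columns).index(variable)
    df = df.drop(columns=[variable])
    for i, (col, vals) in enumerate(new_cols.items()):
        df.insert(pos + i, col, vals)
    del specs[variable]
    return Cohort(df, cohort.outcome, specs)


def expand_families(cohort: Cohort, variables: Iterable[str] | None = None) -> Cohort:
    """One-hot expand every multi-state variable (or the ones listed)."""
    if variables is None:
        variables = [
            v
            for v in cohort.predictors
            if len(cohort.spec(v).observed_states) >= 3
        ]
    out = cohort
    for v in variables:
        out = one_hot(out, v)
    return out


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def summarize(cohort: Cohort) -> pd.DataFrame:
    """Table-style "% (n)" summary of every variable state.

    Percentages use the full cohort size N as denominator (the convention
    of the published cohort tables); unknown states are reported as
    missingness rows flagged in the ``missing`` column.
    """
    rows = []
    n = cohort.n
    for var in cohort.variables:
        counts = cohort.records[var].value_counts()
        for state in cohort.spec(var).states:
            count = int(counts.get(state, 0))
            if state == UNKNOWN and count == 0:
                continue
            pct = round(100.0 * count / n, 1)
            rows.append(
                {
                    "variable": var,
                    "state": state,
                    "count": count,
                    "pct": pct,
                    "cell": f"{pct}% ({count})",
                    "missing": state == UNKNOWN,
                }
            )
    return pd.DataFrame(rows)


def format_cell(count: int, n: int) -> str:
    """Render one "% (n)" summary cell."""
    return f"{round(100.0 * count / n, 1)}% ({count})"
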