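"""Healthy-at-baseline filtering with an auditable exclusion trail.

The analysis restricts to participants who look healthy at recruitment —
no chronic-disease medication, good self-rated health, steady or brisk walk
pace, never/ex-smoker, at most a couple of prior secondary-care episodes and
no prior chronic age-related disease — to reduce reverse causality from
existing illness driving both biomarkers and outcomes.  Rules are data, not
code: thresholds live in the :class:`FilterRule` objects so the same filter
can be re-parameterised.

Each excluded row is attributed to the *first* rule (in declared order) that
it fails, so the audit counts depend on rule order by design and always sum,
together with the retained rows, to the input size.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import pandas as pd

from .errors import SchemaError

__all__ = [
    "FilterRule",
    "default_rules",
    "apply_healthy_filter",
    "admission_risk_set",
]


@dataclass(frozen=True)
class FilterRule:
    """A named eligibility predicate over cohort columns.

    ``predicate`` receives the cohort table and returns a boolean Series that
    is True for rows that PASS the rule.  ``columns`` lists the columns the
    predicate reads, used for upfront schema validation.
    """

    name: str
    columns: tuple[str, ...]
    predicate: Callable[[pd.DataFrame], pd.Series]


def default_rules(max_prior_episodes: int = 2) -> list[FilterRule]:
    """The standard healthy-subpopulation rule set, in audit order."""
    return [
        FilterRule(
            "no_chronic_disease_medication",
            ("on_medication",),
            lambda df: df["on_medication"] == 0,
        ),
        FilterRule(
            "good_self_rated_health",
            ("self_rated_health",),
            lambda df: df["self_rated_health"].isin(["good", "excellent"]),
        ),
        FilterRule(
            "steady_or_brisk_walk_pace",
            ("walk_pace",),
            lambda df: df["walk_pace"].isin(["steady", "brisk"]),
        ),
        FilterRule(
            "never_or_ex_smoker",
            ("smoking",),
            lambda df: df["smoking"].isin(["never", "previous"]),
        ),
        FilterRule(
            "prior_care_episodes",
            ("prior_episodes",),
            lambda df: df["prior_episodes"] <= max_prior_episodes,
        ),
        FilterRule(
            "no_prior_disease_or_fracture",
            ("prior_disease",),
            lambda df: df["prior_disease"] == 0,
        ),
    ]


def apply_healthy_filter(
    cohort: pd.DataFrame, rules: Sequence[FilterRule]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the eligibility rules and return (subcohort, audit).

    The subcohort contains exactly the rows passing every rule.  The audit is
    a two-column table ``(rule, n_excluded)`` attributing each excluded row
    to the first rule it fails; ``len(subcohort) + audit.n_excluded.sum()
    == len(cohort)`` always holds.
    """
    for rule in rules:
        for col in rule.columns:
            if col not in cohort.columns:
                raise SchemaError(f"rule {rule.name!r} needs missing column {col!r}")
    remaining = pd.Series(True, index=cohort.index)
    counts = []
    for rule in rules:
        passes = rule.predicate(cohort).astype(bool)
        newly_excluded = remaining & ~passes
        counts.append((rule.name, int(newly_excluded.sum())))
        remaining &= passes
    audit = pd.DataFrame(counts, columns=["rule", "n_excluded"])
    return cohort.loc[remaining], audit


def admission_risk_set(cohort: pd.DataFrame) -> pd.DataFrame:
    """Risk set for the hospital-admission outcome.

    Participants already admitted with an age-related diagnosis before
    baseline are not at risk of a *first* such admission, so they are dropped
    for the admissions analysis only; mortality analyses use the full table.
    """
    if "prior_admission" not in cohort.columns:
        raise SchemaError("admission_risk_set needs missing column 'prior_admission'")
    return cohort.loc[cohort["prior_admission"] == 0]
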