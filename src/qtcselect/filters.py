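"""Cohort eligibility and healthy-subset selection.

Two row filters, each returning the filtered table together with a
:class:`FilterReport` accounting for every dropped row:

* :func:`apply_eligibility` — drops records with incomplete data, a
  non-sinus rhythm, or a QRS duration above 120 ms (strictly; a QRS of
  exactly 120 ms is retained).
* :func:`select_healthy` — retains subjects with no cardiovascular
  history, no significant medical condition, no QT-affecting medication,
  and an RR interval in the inclusive range 0.5-1.5 s.  This subset is
  the basis for the optimum-correction fits and the normal limits.

A subject failing several criteria is tallied once, under the first
failing criterion in the listed order, so reports are deterministic and
their exclusion counts sum to ``n_input - n_output``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = ["FilterReport", "apply_eligibility", "select_healthy", "recompute_qt_drug"]

ELIGIBILITY_COLUMNS = ["sinus_rhythm", "qrs"]
REQUIRED_FIELDS = ["male", "age", "hr", "rr", "qt", "qrs", "sinus_rhythm"]
HEALTHY_FLAGS = ["cvd_history", "medical_condition", "qt_drug"]
RR_HEALTHY_RANGE = (0.5, 1.5)


@dataclass
class FilterReport:
    """Accounting of a filtering pass."""

    n_input: int
    n_output: int
    exclusions: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_input != self.n_output + sum(self.exclusions.values()):
            raise ValueError("exclusion counts do not sum to n_input - n_output")

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_output": self.n_output,
            "exclusions": dict(self.exclusions),
        }


def _first_failure_counts(fail_masks: dict[str, pd.Series]) -> tuple[pd.Series, dict[str, int]]:
    """Combine per-criterion failure masks, tallying each row once."""
    counts: dict[str, int] = {}
    already = None
    for name, mask in fail_masks.items():
        fresh = mask if already is None else (mask & ~already)
        counts[name] = int(fresh.sum())
        already = mask if already is None else (already | mask)
    return already, counts


def apply_eligibility(cohort: pd.DataFrame) -> tuple[pd.DataFrame, FilterReport]:
    """Drop incomplete, non-sinus, or wide-QRS (> 120 ms) records."""
    missing_cols = set(ELIGIBILITY_COLUMNS) - set(cohort.columns)
    if missing_cols:
        raise ValueError(f"cohort is missing required columns: {sorted(missing_cols)}")
    if len(cohort) == 0:
        report = FilterReport(0, 0, {"missing_fields": 0, "non_sinus": 0, "qrs_gt_120": 0})
        return cohort.copy(), report

    present = [c for c in REQUIRED_FIELDS if c in cohort.columns]
    fail = {
        "missing_fields": cohort[present].isna().any(axis=1),
        "non_sinus": ~cohort["sinus_rhythm"].astype(bool),
        "qrs_gt_120": cohort["qrs"] > 120.0,
    }
    any_fail, counts = _first_failure_counts(fail)
    kept = cohort.loc[~any_fail].copy()
    return kept, FilterReport(len(cohort), len(kept), counts)


def select_healthy(cohort: pd.DataFrame) -> tuple[pd.DataFrame, FilterReport]:
    """Retain flag-free subjects with RR in [0.5, 1.5] s (inclusive)."""
    missing_cols = (set(HEALTHY_FLAGS) | {"rr"}) - set(cohort.columns)
    if missing_cols:
        raise ValueError(f"cohort is missing required columns: {sorted(missing_cols)}")
    lo, hi = RR_HEALTHY_RANGE
    if len(cohort) == 0:
        names = HEALTHY_FLAGS + ["rr_out_of_range"]
        return cohort.copy(), FilterReport(0, 0, {n: 0 for n in names})

    fail = {name: cohort[name].astype(bool) for name in HEALTHY_FLAGS}
    fail["rr_out_of_range"] = (cohort["rr"] < lo) | (cohort["rr"] > hi)
    any_fail, counts = _first_failure_counts(fail)
    kept = cohort.loc[~any_fail].copy()
    return kept, FilterReport(len(cohort), len(kept), counts)


def recompute_qt_drug(
    cohort: pd.DataFrame, drug_list: set[str], medication_column: str = "medication"
) -> pd.DataFrame:
    """Recompute the ``qt_drug`` flag from a user-supplied drug-name list.

    If ``medication_column`` holds a delimited string of drug names per
    subject, ``qt_drug`` becomes 1 iff any name (case-insensitive) is in
    ``drug_list``.  Without such a column the boolean flag is trusted and
    the table is returned unchanged.
    """
    if medication_column not in cohort.columns:
        return cohort
    names = {d.strip().lower() for d in drug_list}
    out = cohort.copy()

    def _hit(cell) -> int:
        if not isinstance(cell, str) or not cell.strip():
            return 0
        return int(any(tok.strip().lower() in names for tok in cell.split(";")))

    out["qt_drug"] = out[medication_column].map(_hit)
    return out
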