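"""Cohort summary tables and 2x2 association tests.

Associations between categorical patient attributes (immunophenotype,
molecular subtype) and per-patient outcomes (clonal evolution, mechanism
class) are tested with Fisher's exact test, two-sided by the
minimum-likelihood rule (the default of R's ``fisher.test``): the
p-value sums the hypergeometric probabilities, over all tables with the
observed margins, of every table whose point probability does not
exceed that of the observed table.  p-values are reported raw; a
Benjamini-Hochberg option exists but is off by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy import stats as sps

__all__ = [
    "ContingencyTable2x2",
    "CohortSummary",
    "fisher_exact_2x2",
    "summarize_cohort",
    "associate",
    "PatientResult",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts [[a, b], [c, d]]; rows = groups, columns = outcome yes/no."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("negative cell count")
        if self.total == 0:
            raise ValueError("empty table")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


def fisher_exact_2x2(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher's exact p-value (minimum-likelihood rule).

    A table with a zero margin carries no information about association;
    p = 1 by convention (with a warning).
    """
    arr = table.as_array()
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        warnings.warn("zero margin in 2x2 table; p = 1 by convention")
        return 1.0
    _, p = sps.fisher_exact(arr, alternative="two-sided")
    return float(min(p, 1.0))


@dataclass(frozen=True)
class PatientResult:
    """Per-patient rollup consumed by the cohort summary."""

    patient_id: str
    n_marker_stems: int
    has_evolving: bool
    mechanism_counts: Tuple[Tuple[str, int], ...] = ()


@dataclass
class CohortSummary:
    n_patients: int
    n_with_marker: int
    n_no_marker: int
    n_evolving: int
    n_stable: int
    n_marker_stems: int
    stems_per_patient_mean: float
    mechanism_breakdown: Dict[str, int]


def summarize_cohort(results: Sequence[PatientResult]) -> CohortSummary:
    """Cohort rollup: a patient is *evolving* with >= 1 evolving stem in
    any library, *stable* with markers but no evolving stem, *no marker*
    with zero marker stems.  Mean stems/patient is over marker-positive
    patients."""
    if not results:
        raise ValueError("empty cohort")
    with_marker = [r for r in results if r.n_marker_stems > 0]
    evolving = [r for r in with_marker if r.has_evolving]
    mech: Dict[str, int] = {}
    for r in results:
        for name, n in r.mechanism_counts:
            mech[name] = mech.get(name, 0) + n
    n_stems = sum(r.n_marker_stems for r in with_marker)
    return CohortSummary(
        n_patients=len(results),
        n_with_marker=len(with_marker),
        n_no_marker=len(results) - len(with_marker),
        n_evolving=len(evolving),
        n_stable=len(with_marker) - len(evolving),
        n_marker_stems=n_stems,
        stems_per_patient_mean=n_stems / len(with_marker) if with_marker else 0.0,
        mechanism_breakdown=mech,
    )


def associate(attribute: Dict[str, str], outcome: Dict[str, bool],
              groups: Tuple[str, str]) -> Tuple[ContingencyTable2x2, float]:
    """2x2 association between a two-level patient attribute and a boolean
    per-patient outcome.

    ``attribute`` and ``outcome`` map patient id to category / outcome;
    every patient with an attribute in ``groups`` must have an outcome.
    Returns the assembled table and the two-sided Fisher p-value.
    """
    g1, g2 = groups
    counts = {g1: [0, 0], g2: [0, 0]}
    for patient, cat in attribute.items():
        if cat not in counts:
            continue
        if patient not in outcome:
            raise ValueError(f"patient {patient!r} has attribute but no outcome")
        counts[cat][0 if outcome[patient] else 1] += 1
    if sum(counts[g1]) == 0 or sum(counts[g2]) == 0:
        raise ValueError(f"a group in {groups} has zero patients")
    table = ContingencyTable2x2(a=counts[g1][0], b=counts[g1][1],
                                c=counts[g2][0], d=counts[g2][1])
    return table, fisher_exact_2x2(table)
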