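"""2×2 report-count tables for (drug, term-set) pairs.

Disproportionality statistics compare how often a drug and an event class
are reported together against the whole-database background.  Every
deduplicated case falls in exactly one cell:

    a  drug and ≥1 included event PT       b  drug, no included event PT
    c  event without the drug              d  neither

The counting unit is the report: a case carrying two seizure PTs still
contributes one count to ``a``.  Drug exposure defaults to the Primary
Suspected (PS) role only.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import FrozenSet, Iterable, Sequence

from .faers_io import CaseReport
from .vocabulary import TermSet

PS_ONLY: frozenset[str] = frozenset({"PS"})
ALL_ROLES: frozenset[str] = frozenset({"PS", "SS", "C", "I"})


@dataclass(frozen=True)
class ContingencyTable:
    drug: str
    term_set: str
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("negative cell count")

    @property
    def n_total(self) -> int:
        return self.a + self.b + self.c + self.d


def case_has_drug(case: CaseReport, drug: str, role_filter: FrozenSet[str] = PS_ONLY) -> bool:
    """True iff the case carries ``drug`` (an ATC code) in an accepted role."""
    return any(e.atc_code == drug and e.role in role_filter for e in case.drugs)


def case_has_event(case: CaseReport, term_set: TermSet) -> bool:
    """True iff any *reported event* PT is in the set's inclusions.

    Indication PTs are deliberately not consulted: an indication is why the
    drug was given, not what happened to the patient.
    """
    return not case.event_pts.isdisjoint(term_set.included_pts)


def build_table(
    cases: Sequence[CaseReport],
    drug: str,
    term_set: TermSet,
    role_filter: FrozenSet[str] = PS_ONLY,
) -> ContingencyTable:
    """Classify every case into exactly one cell of the 2×2 table."""
    if not cases:
        raise ValueError("cannot build a contingency table from zero cases")
    a = b = c = d = 0
    for case in cases:
        has_drug = case_has_drug(case, drug, role_filter)
        has_event = case_has_event(case, term_set)
        if has_drug:
            if has_event:
                a += 1
            else:
                b += 1
        elif has_event:
            c += 1
        else:
            d += 1
    table = ContingencyTable(drug, term_set.name, a, b, c, d)
    assert table.n_total == len(cases), "cell partition lost a case"
    return table


def build_tables(
    cases: Sequence[CaseReport],
    drugs: Iterable[str],
    term_set: TermSet,
    role_filter: FrozenSet[str] = PS_ONLY,
) -> dict[str, ContingencyTable]:
    """One-pass construction of the 2×2 tables for many drugs.

    Equivalent to calling :func:`build_table` per drug but classifies each
    case once, which matters when screening a 65-drug dictionary over 10⁵+
    cases.
    """
    if not cases:
        raise ValueError("cannot build contingency tables from zero cases")
    drugs = list(drugs)
    wanted = set(drugs)
    n = len(cases)
    n_event = 0
    drug_n: Counter[str] = Counter()
    drug_event: Counter[str] = Counter()
    for case in cases:
        has_event = case_has_event(case, term_set)
        if has_event:
            n_event += 1
        seen = {e.atc_code for e in case.drugs if e.role in role_filter and e.atc_code in wanted}
        for atc in seen:
            drug_n[atc] += 1
            if has_event:
                drug_event[atc] += 1
    out = {}
    for drug in drugs:
        a = drug_event[drug]
        b = drug_n[drug] - a
        c = n_event - a
        d = n - drug_n[drug] - c
        out[drug] = ContingencyTable(drug, term_set.name, a, b, c, d)
    return out
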