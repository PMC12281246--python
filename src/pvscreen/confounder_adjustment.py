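"""Confounding-by-indication sensitivity reanalysis.

A drug prescribed for a condition that itself produces the event (e.g. an
antidepressant given to a patient with epilepsy) inflates the apparent
drug–event association.  The sensitivity analysis removes every report
that carries a confounder-category PT — as a reported event *or* as a drug
indication — and reruns the screen on the remainder.  Flagged reports are
dropped from the whole table (all four cells), not just the co-report
cell, since leaving them in the background would bias the comparator.

A primary signal that survives is a ``robust_signal``; one that vanishes
post-exclusion is a ``false_signal`` attributable to confounding.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import FrozenSet, Sequence

from .contingency import PS_ONLY, case_has_drug
from .disproportionality import ScreenResult, SignalStatistics, compute_statistics, run_screen
from .contingency import ContingencyTable
from .faers_io import CaseReport
from .vocabulary import ConfounderCatalog, DrugDictionary, TermSet

logger = logging.getLogger(__name__)

ROBUST_SIGNAL = "robust_signal"
FALSE_SIGNAL = "false_signal"
NO_PRIMARY_SIGNAL = "no_primary_signal"


@dataclass(frozen=True)
class AdjustedSignal:
    drug: str
    primary: SignalStatistics
    adjusted: SignalStatistics
    excluded_case_count: int
    verdict: str


@dataclass
class ReanalysisResult:
    adjusted_signals: list[AdjustedSignal]
    primary: ScreenResult
    adjusted: ScreenResult
    n_excluded: int
    n_cases: int


def flag_confounded(case: CaseReport, catalog: ConfounderCatalog) -> bool:
    """True iff any reported-event or indication PT falls in a confounder category."""
    pts = case.event_pts | case.indication_pts
    return any(not pts.isdisjoint(cat.included_pts) for cat in catalog.categories)


def _verdict(primary: SignalStatistics, adjusted: SignalStatistics) -> str:
    if not primary.is_signal:
        return NO_PRIMARY_SIGNAL
    return ROBUST_SIGNAL if adjusted.is_signal else FALSE_SIGNAL


def reanalyze(
    cases: Sequence[CaseReport],
    dictionary: DrugDictionary,
    term_set: TermSet,
    catalog: ConfounderCatalog,
    role_filter: FrozenSet[str] = PS_ONLY,
    min_cases: int = 3,
    continuity: bool = False,
) -> ReanalysisResult:
    """Run the primary screen, exclude confounded reports, rerun, and compare.

    The per-drug ``excluded_case_count`` counts flagged reports carrying
    that drug; ``n_excluded`` counts all flagged reports.  Excluding every
    report is fatal — a catalog that swallows the database cannot support a
    reanalysis.
    """
    flags = [flag_confounded(c, catalog) for c in cases]
    kept = [c for c, f in zip(cases, flags) if not f]
    n_excluded = len(cases) - len(kept)
    if not kept:
        raise ValueError(
            f"confounder exclusion removed all {len(cases)} reports; "
            "check the catalog against the event background"
        )
    logger.info("confounder exclusion removed %d of %d reports", n_excluded, len(cases))

    primary = run_screen(cases, dictionary, term_set, role_filter, min_cases, continuity)
    adjusted = run_screen(kept, dictionary, term_set, role_filter, min_cases, continuity)
    adjusted_by_drug = {s.drug: s for s in adjusted.signals}

    excluded_per_drug: dict[str, int] = {}
    for case, flagged in zip(cases, flags):
        if not flagged:
            continue
        for entry in case.drugs:
            if entry.role in role_filter and entry.atc_code is not None:
                excluded_per_drug[entry.atc_code] = excluded_per_drug.get(entry.atc_code, 0) + 1

    n_kept_event = sum(
        1 for c in kept if not c.event_pts.isdisjoint(term_set.included_pts)
    )
    out: list[AdjustedSignal] = []
    for s in primary.signals:
        adj = adjusted_by_drug.get(s.drug)
        if adj is None:
            # drug lost all co-reports: its adjusted table has a = 0
            n_drug = sum(1 for c in kept if case_has_drug(c, s.drug, role_filter))
            table = ContingencyTable(
                s.drug, term_set.name,
                0, n_drug, n_kept_event, len(kept) - n_drug - n_kept_event,
            )
            adj = compute_statistics(table, min_cases, continuity)
        out.append(
            AdjustedSignal(
                drug=s.drug,
                primary=s,
                adjusted=adj,
                excluded_case_count=excluded_per_drug.get(s.drug, 0),
                verdict=_verdict(s, adj),
            )
        )
    return ReanalysisResult(out, primary, adjusted, n_excluded, len(cases))


def adjusted_frame(result: ReanalysisResult, dictionary: DrugDictionary):
    """TSV-ready comparison of primary vs adjusted statistics with verdicts."""
    import pandas as pd

    rows = []
    for s in result.adjusted_signals:
        p, a = s.primary, s.adjusted
        rows.append({
            "drug_atc": s.drug,
            "drug_label": dictionary.label(s.drug),
            "a": p.a, "ror": round(p.ror, 2), "ror_low": round(p.ror_low, 2),
            "ror_high": round(p.ror_high, 2), "ic": round(p.ic, 2),
            "ic_low": round(p.ic_low, 2), "is_signal": p.is_signal,
            "a_adjusted": a.a, "ror_adjusted": round(a.ror, 2),
            "ror_low_adjusted": round(a.ror_low, 2), "ror_high_adjusted": round(a.ror_high, 2),
            "ic_adjusted": round(a.ic, 2), "ic_low_adjusted": round(a.ic_low, 2),
            "is_signal_adjusted": a.is_signal,
            "excluded_cases": s.excluded_case_count,
            "verdict": s.verdict,
        })
    return pd.DataFrame(rows)
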