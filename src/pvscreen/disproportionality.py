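"""Reporting odds ratio, shrinkage information component, and the joint signal rule.

Two complementary disproportionality statistics are computed from each 2×2
table:

* **ROR** — the reporting odds ratio ``(a·d)/(b·c)`` with a Woolf/Wald 95 %
  interval on the log scale, ``exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d))``.
  Sensitive for frequently reported events.
* **IC** — a shrinkage information component measuring, in bits, how far the
  observed co-reporting count ``a`` exceeds its independence expectation
  ``E = (a+b)(a+c)/n``:  ``IC = log2((a+0.5)/(E+0.5))``, with closed-form
  95 % credibility bounds
  ``IC ± {3.3, −2.4}·(a+0.5)^(−1/2) ∓ {2, 0.5}·(a+0.5)^(−3/2)``.
  The +0.5 shrinkage stabilises rare events; it vanishes as ``a`` grows, so
  IC → log2(observed/expected) asymptotically.

A drug–event pair is a *signal* only when every criterion holds strictly:
at least ``min_cases`` co-reports (default 3), ROR lower 95 % bound > 1,
IC > 0, and IC lower 95 % bound > 0.  The conjunction trades a little
sensitivity for far fewer single-case false alarms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import FrozenSet, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .contingency import PS_ONLY, ContingencyTable, build_tables
from .faers_io import CaseReport
from .vocabulary import DrugDictionary, TermSet

Z95 = 1.96  # two-sided 95% normal quantile, by pharmacovigilance convention


class RorEstimate(NamedTuple):
    ror: float
    low: float
    high: float


class IcEstimate(NamedTuple):
    ic: float
    low: float
    high: float


@dataclass(frozen=True)
class SignalStatistics:
    """Point estimates, interval bounds and the joint verdict for one pair."""

    drug: str
    term_set: str
    a: int
    b: int
    c: int
    d: int
    ror: float
    ror_low: float
    ror_high: float
    ic: float
    ic_low: float
    ic_high: float
    is_signal: bool


def compute_ror(table: ContingencyTable, continuity: bool = False) -> RorEstimate:
    """ROR with its Wald 95 % CI.

    ``continuity=True`` applies the Haldane–Anscombe correction (+0.5 to
    every cell) when any cell is zero, keeping the estimate finite.  With
    the correction off, a zero cell yields the raw ratio (0 or inf) and the
    uninformative interval (0, inf).
    """
    a, b, c, d = (float(x) for x in (table.a, table.b, table.c, table.d))
    if b == 0 and c == 0 and d == 0:
        raise ValueError("degenerate table: all background cells are zero")
    if continuity and min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    if min(a, b, c, d) == 0:
        if a == 0 or d == 0:
            point = 0.0 if (b > 0 and c > 0) else math.nan
        else:
            point = math.inf
        return RorEstimate(point, 0.0, math.inf)
    point = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_ror = math.log(point)
    return RorEstimate(point, math.exp(log_ror - Z95 * se), math.exp(log_ror + Z95 * se))


def compute_ic(table: ContingencyTable) -> IcEstimate:
    """Shrinkage IC (bits) with closed-form 95 % credibility bounds."""
    n = table.n_total
    if n <= 0:
        raise ValueError("empty table")
    a = float(table.a)
    expected = (table.a + table.b) * (table.a + table.c) / n
    ic = math.log2((a + 0.5) / (expected + 0.5))
    s = a + 0.5
    low = ic - 3.3 * s ** -0.5 - 2.0 * s ** -1.5
    high = ic + 2.4 * s ** -0.5 - 0.5 * s ** -1.5
    return IcEstimate(ic, low, high)


def evaluate_signal(
    a: int, ror_low: float, ic: float, ic_low: float, min_cases: int = 3
) -> bool:
    """Strict conjunction of the case-count, ROR and IC criteria."""
    return a >= min_cases and ror_low > 1.0 and ic > 0.0 and ic_low > 0.0


def compute_statistics(
    table: ContingencyTable, min_cases: int = 3, continuity: bool = False
) -> SignalStatistics:
    ror = compute_ror(table, continuity)
    ic = compute_ic(table)
    return SignalStatistics(
        drug=table.drug,
        term_set=table.term_set,
        a=table.a, b=table.b, c=table.c, d=table.d,
        ror=ror.ror, ror_low=ror.low, ror_high=ror.high,
        ic=ic.ic, ic_low=ic.low, ic_high=ic.high,
        is_signal=evaluate_signal(table.a, ror.low, ic.ic, ic.low, min_cases),
    )


@dataclass
class ScreenResult:
    """Ranked statistics for drugs with ≥1 co-report, plus the zero-count rest."""

    signals: list[SignalStatistics]
    zero_case_drugs: list[str]
    term_set: str


def run_screen(
    cases: Sequence[CaseReport],
    dictionary: DrugDictionary,
    term_set: TermSet,
    role_filter: FrozenSet[str] = PS_ONLY,
    min_cases: int = 3,
    continuity: bool = False,
) -> ScreenResult:
    """Screen every dictionary drug against one term set.

    Returns one :class:`SignalStatistics` per drug with at least one
    co-report, ranked by descending ROR (ties broken by display label);
    drugs never co-reported with the event are listed separately.
    """
    tables = build_tables(cases, dictionary.atc_codes, term_set, role_filter)
    stats = [
        compute_statistics(t, min_cases, continuity)
        for t in tables.values()
        if t.a >= 1
    ]

    def sort_key(s: SignalStatistics) -> tuple[float, str]:
        ror = s.ror if not math.isnan(s.ror) else -math.inf
        return (-ror, dictionary.label(s.drug))

    stats.sort(key=sort_key)
    zero = sorted(
        (d for d, t in tables.items() if t.a == 0), key=dictionary.label
    )
    return ScreenResult(stats, zero, term_set.name)


def signal_frame(result: ScreenResult, dictionary: DrugDictionary) -> pd.DataFrame:
    """Tabular export: 2-decimal display columns plus full-precision companions."""
    rows = []
    for s in result.signals:
        rows.append({
            "drug_atc": s.drug,
            "drug_label": dictionary.label(s.drug),
            "a": s.a, "b": s.b, "c": s.c, "d": s.d,
            "ror": round(s.ror, 2), "ror_low": round(s.ror_low, 2), "ror_high": round(s.ror_high, 2),
            "ic": round(s.ic, 2), "ic_low": round(s.ic_low, 2), "ic_high": round(s.ic_high, 2),
            "is_signal": s.is_signal,
            "ror_full": s.ror, "ror_low_full": s.ror_low, "ror_high_full": s.ror_high,
            "ic_full": s.ic, "ic_low_full": s.ic_low, "ic_high_full": s.ic_high,
        })
    return pd.DataFrame(rows)


def write_signal_table(result: ScreenResult, dictionary: DrugDictionary, path) -> None:
    signal_frame(result, dictionary).to_csv(path, sep="\t", index=False)
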