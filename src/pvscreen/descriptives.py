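"""Demographic summaries of event cases and per-drug constituent ratios.

All percentages follow the half-up rounding convention (0.5 rounds away
from zero), which reproduces published stratum percentages from their
integer counts; banker's rounding does not.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

from .faers_io import CaseReport

DIMENSIONS = ("sex", "age_band", "reporter", "region")

STRATUM_ORDER: dict[str, list[str]] = {
    "sex": ["female", "male", "unknown"],
    "age_band": ["<18", "18-65", ">=65", "unknown"],
    "reporter": ["health_professional", "non_health_professional", "unknown"],
    "region": ["Europe", "NorthAmerica", "Asia", "Oceania", "SouthAmerica", "Africa", "unknown"],
}


def round_half_up(x: float, ndigits: int) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def _percent(count: int, total: int, ndigits: int = 1) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float((Decimal(100 * count) / Decimal(total)).quantize(q, rounding=ROUND_HALF_UP))


def age_band(age_years: float | None) -> str:
    """Band edges: <18, 18–65 (18 ≤ age < 65), ≥65; missing age → unknown."""
    if age_years is None:
        return "unknown"
    if age_years < 18:
        return "<18"
    if age_years < 65:
        return "18-65"
    return ">=65"


@dataclass(frozen=True)
class DescriptiveSummary:
    dimension: str
    rows: tuple[tuple[str, int, float], ...]  # (stratum label, count, percent)
    total: int

    @classmethod
    def from_counts(cls, dimension: str, counts: Mapping[str, int]) -> "DescriptiveSummary":
        """Build a summary from stratum counts (e.g. a published table's numbers)."""
        total = sum(counts.values())
        if total == 0:
            raise ValueError("cannot summarize zero cases")
        rows = tuple((label, n, _percent(n, total)) for label, n in counts.items())
        return cls(dimension, rows, total)


def _stratum(case: CaseReport, dimension: str) -> str:
    if dimension == "sex":
        return case.sex
    if dimension == "age_band":
        return age_band(case.age_years)
    if dimension == "reporter":
        return case.reporter
    if dimension == "region":
        return case.region
    raise ValueError(f"unknown dimension {dimension!r}")


def summarize(cases_with_event: Sequence[CaseReport], dimension: str) -> DescriptiveSummary:
    """Stratum counts and percentages over cases already restricted to the event.

    Every stratum of the dimension appears, including an explicit
    ``unknown`` row, in a fixed display order.
    """
    if not cases_with_event:
        raise ValueError("cannot summarize zero cases")
    counts = {label: 0 for label in STRATUM_ORDER[dimension]}
    for case in cases_with_event:
        counts[_stratum(case, dimension)] += 1
    return DescriptiveSummary.from_counts(dimension, counts)


def constituent_ratio(n_event_reports: int, n_all_reports_for_drug: int) -> float:
    """Percentage of one drug's reports that are the event of interest (2 dp)."""
    if n_all_reports_for_drug <= 0:
        raise ValueError("drug has no reports")
    if not 0 <= n_event_reports <= n_all_reports_for_drug:
        raise ValueError("event count outside [0, total]")
    return float(
        (Decimal(100 * n_event_reports) / Decimal(n_all_reports_for_drug))
        .quantize(Decimal("0.01"), rounding=ROUND_HALF_UP)
    )


def sex_ratio(n_female: int, n_male: int) -> float:
    """Female:male reporting ratio, rounded half-up to 2 decimals."""
    if n_male <= 0:
        raise ValueError("male count must be positive")
    return float(
        (Decimal(n_female) / Decimal(n_male)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP)
    )


def render_markdown(summary: DescriptiveSummary) -> str:
    lines = [
        f"### {summary.dimension}",
        "",
        "| stratum | n | % |",
        "| --- | ---: | ---: |",
    ]
    for label, n, pct in summary.rows:
        lines.append(f"| {label} | {n} | {pct:.1f} |")
    lines.append(f"| **total** | {summary.total} | 100 |")
    return "\n".join(lines) + "\n"
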