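"""Descriptive summaries and formatted signal tables.

``describe`` produces the stratum counts and percentages conventionally
tabulated for a spontaneous-report corpus (sex, age band, reporter type,
country, report year, serious outcomes); ``signal_report`` renders the
scored drug-event pairs the way signal-mining papers print them, ranked by
EBGM with "estimate (low-high)" interval columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import pandas as pd

from .faers_io import CaseReport
from .signal_stats import ScoredRow

AGE_BANDS = ("<18", "18-45", "45-65", "65-75", ">=75")

_SEX_LABELS = {"F": "Female", "M": "Male"}
_OUTCOME_ORDER = ("DE", "LT", "HO", "DS", "CA", "RI", "OT")


def pct(count: int, total: int) -> float:
    """Percentage rounded half-up to 2 decimals, as printed in report tables."""
    if total == 0:
        return 0.0
    return float((Decimal(count) * 100 / Decimal(total)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def age_band(age: float | None) -> str:
    if age is None:
        return "Unknown"
    if age < 18:
        return "<18"
    if age < 45:
        return "18-45"
    if age < 65:
        return "45-65"
    if age < 75:
        return "65-75"
    return ">=75"


@dataclass
class DescriptiveSummary:
    """Per-factor stratum counts and percentages.

    ``factors`` maps factor name to an ordered list of (stratum, count,
    percentage). Single-valued factors (gender, age, reporter, country,
    year) sum to ``total_reports``; outcomes are counted per report and a
    report may carry several outcome codes, so the outcome strata need not
    sum to the total.
    """

    total_reports: int
    factors: dict[str, list[tuple[str, int, float]]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        records = [
            {"factor": factor, "stratum": stratum, "count": count, "percent": p}
            for factor, rows in self.factors.items()
            for stratum, count, p in rows
        ]
        return pd.DataFrame.from_records(records, columns=["factor", "stratum", "count", "percent"])


def _tally(values: Iterable[str], total: int, order: Sequence[str] = ()) -> list[tuple[str, int, float]]:
    counts: dict[str, int] = {}
    for v in values:
        counts[v] = counts.get(v, 0) + 1
    ordered = [s for s in order if s in counts]
    ordered += sorted(s for s in counts if s not in ordered and s != "Unknown")
    if "Unknown" in counts and "Unknown" not in ordered:
        ordered.append("Unknown")
    return [(s, counts[s], pct(counts[s], total)) for s in ordered]


def describe(reports: Sequence[CaseReport]) -> DescriptiveSummary:
    """Stratum counts and percentages for a deduplicated report set.

    Missing values fall into an "Unknown" stratum; percentages are of the
    total report count, rounded half-up to 2 decimals.
    """
    total = len(reports)
    summary = DescriptiveSummary(total_reports=total)
    if total == 0:
        return summary

    summary.factors["gender"] = _tally(
        (_SEX_LABELS.get(r.sex, "Unknown") for r in reports), total, order=("Female", "Male")
    )
    summary.factors["age"] = _tally((age_band(r.age) for r in reports), total, order=AGE_BANDS)
    summary.factors["reporter"] = _tally(
        (r.reporter.capitalize() if r.reporter != "UNK" else "Unknown" for r in reports),
        total,
        order=("Consumer", "Physician", "Pharmacist", "Other"),
    )
    summary.factors["country"] = _tally((r.country if r.country else "Unknown" for r in reports), total)
    summary.factors["report_year"] = _tally(
        (str(r.fda_date.year) if r.fda_date else "Unknown" for r in reports), total
    )
    outcome_counts = {code: sum(1 for r in reports if code in r.outcomes) for code in _OUTCOME_ORDER}
    summary.factors["serious_outcome"] = [
        (code, cnt, pct(cnt, total)) for code, cnt in outcome_counts.items() if cnt
    ]
    return summary


def _interval(value: float, low: float, high: float) -> str:
    return f"{value:.2f} ({low:.2f}–{high:.2f})"


def signal_report(rows: Sequence[ScoredRow], top_n: int = 30, level: str = "PT") -> pd.DataFrame:
    """Render scored pairs as a publication-style table.

    At PT level only pairs flagged by all four algorithms are shown; at SOC
    level every SOC is reported with its scores. Rows are sorted by EBGM
    descending (ties by event id) and truncated to ``top_n``.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    selected = [r for r in rows if r.level == level and r.scores is not None]
    if level == "PT":
        selected = [r for r in selected if r.decision is not None and r.decision.pass_all]
    selected.sort(key=lambda r: (-r.scores.ebgm, r.event_id))
    selected = selected[:top_n]
    records = []
    for r in selected:
        s = r.scores
        records.append(
            {
                "event_id": r.event_id,
                "case_reports": r.table.a,
                "ror_95ci": _interval(s.ror, *s.ror_ci95),
                "prr_95ci": _interval(s.prr, *s.prr_ci95),
                "chi2": f"{s.chi2:.2f}",
                "ic_ic025": f"{s.ic:.2f} ({s.ic025:.2f})",
                "ebgm_ebgm05": f"{s.ebgm:.2f} ({s.ebgm05:.2f})",
            }
        )
    columns = ["event_id", "case_reports", "ror_95ci", "prr_95ci", "chi2", "ic_ic025", "ebgm_ebgm05"]
    return pd.DataFrame.from_records(records, columns=columns)
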