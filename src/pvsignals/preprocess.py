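"""Screening of assembled case reports ahead of disproportionality analysis.

The screening pipeline mirrors standard spontaneous-report practice: restrict
to a receipt-date window, keep only the latest version of each case,
optionally drop reports with no usable patient information at all, and split
the survivors into target-drug reports (drug of interest as primary suspect)
and the background corpus that every 2x2 table is computed against.
"""

from __future__ import annotations

import datetime
import logging
import re
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

from .faers_io import CaseReport, MeddraMap, Reaction

logger = logging.getLogger(__name__)

UNMAPPED = "UNMAPPED"

_QUARTER_RE = re.compile(r"^(\d{4})Q([1-4])$")


class ConfigError(ValueError):
    """Invalid screening configuration."""


def parse_quarter(label: str) -> tuple[int, int]:
    """``"2020Q2" -> (2020, 2)``."""
    m = _QUARTER_RE.match(label.strip().upper())
    if not m:
        raise ConfigError(f"quarter label {label!r} does not match YYYYQn")
    return int(m.group(1)), int(m.group(2))


def quarter_of(date: datetime.date) -> tuple[int, int]:
    return date.year, (date.month - 1) // 3 + 1


@dataclass(frozen=True)
class ScreeningConfig:
    """Parameters of the report-screening stage.

    ``drug_synonyms`` are matched as case-insensitive substrings of both the
    verbatim drug name and the active-ingredient field, because spontaneous
    reports carry free-text names with dose and formulation suffixes.
    ``min_pair_count`` is the minimum report count ``a`` for a drug-event
    pair to be eligible for signal evaluation (the classical ``a >= 3``
    screen); it is applied at scoring time, not as a per-case filter.
    """

    drug_synonyms: Sequence[str] = ("TABRECTA", "CAPMATINIB")
    require_primary_suspect: bool = True
    min_pair_count: int = 3
    exclude_missing_all_demographics: bool = True
    date_window: tuple[str, str] = ("2020Q2", "2023Q4")

    def validate(self) -> None:
        if not self.drug_synonyms:
            raise ConfigError("drug_synonyms must be non-empty")
        if self.min_pair_count < 1:
            raise ConfigError("min_pair_count must be >= 1")
        start, end = (parse_quarter(q) for q in self.date_window)
        if start > end:
            raise ConfigError(f"empty date window: {self.date_window[0]} > {self.date_window[1]}")


@dataclass
class ScreenedDataset:
    """Survivors of screening, split into target and background reports.

    ``screening_log`` accounts for every input report:
    ``input = removed_* ... + retained_target + retained_background``.
    """

    target_reports: list[CaseReport]
    background_reports: list[CaseReport]
    screening_log: dict[str, int] = field(default_factory=dict)


def deduplicate(cases: Iterable[CaseReport]) -> list[CaseReport]:
    """Keep exactly one record per caseid: the highest caseversion, ties
    broken by latest FDA receipt date, then lexicographically largest
    primaryid. Idempotent and insensitive to input order; output is sorted
    by caseid for determinism."""
    best: dict[str, CaseReport] = {}
    for case in cases:
        key = (case.caseversion, case.fda_date or datetime.date.min, case.primaryid)
        kept = best.get(case.caseid)
        if kept is None or key > (kept.caseversion, kept.fda_date or datetime.date.min, kept.primaryid):
            best[case.caseid] = case
    return [best[cid] for cid in sorted(best)]


def _name_matches(text: str, synonyms: Sequence[str]) -> bool:
    folded = text.casefold()
    return any(s in folded for s in synonyms)


def match_target_drug(case: CaseReport, cfg: ScreeningConfig) -> bool:
    """True iff some drug record matches a synonym (substring, case-folded,
    on drug name or active ingredient) and — when ``require_primary_suspect``
    — that same record carries the PS role code."""
    synonyms = tuple(s.strip().casefold() for s in cfg.drug_synonyms)
    for rec in case.drugs:
        if _name_matches(rec.drugname, synonyms) or _name_matches(rec.prod_ai, synonyms):
            if not cfg.require_primary_suspect or rec.role_code == "PS":
                return True
    return False


def _missing_all_demographics(case: CaseReport) -> bool:
    return (
        case.sex == "UNK"
        and case.age is None
        and (not case.country)
        and case.reporter == "UNK"
    )


def _in_window(case: CaseReport, start: tuple[int, int], end: tuple[int, int]) -> bool:
    # receipt quarter; a missing receipt date cannot justify exclusion
    if case.fda_date is None:
        return True
    return start <= quarter_of(case.fda_date) <= end


def screen(cases: Iterable[CaseReport], cfg: ScreeningConfig) -> ScreenedDataset:
    """Run the full screening pipeline.

    Order: date-window filter -> deduplication -> missing-information
    exclusion (a report is dropped only when sex, age, country and reporter
    are all missing, and only if enabled) -> target/background split.
    Every removal is logged by reason.
    """
    cfg.validate()
    cases = list(cases)
    log: dict[str, int] = {"input": len(cases)}

    start, end = (parse_quarter(q) for q in cfg.date_window)
    in_window = [c for c in cases if _in_window(c, start, end)]
    log["removed_out_of_window"] = len(cases) - len(in_window)

    unique = deduplicate(in_window)
    log["removed_duplicate"] = len(in_window) - len(unique)

    if cfg.exclude_missing_all_demographics:
        complete = [c for c in unique if not _missing_all_demographics(c)]
    else:
        complete = unique
    log["removed_missing_info"] = len(unique) - len(complete)

    target = [c for c in complete if match_target_drug(c, cfg)]
    background = [c for c in complete if not match_target_drug(c, cfg)]
    log["retained_target"] = len(target)
    log["retained_background"] = len(background)
    logger.info("screening log: %s", log)
    return ScreenedDataset(target_reports=target, background_reports=background, screening_log=log)


def annotate_soc(
    cases: Iterable[CaseReport], meddra: MeddraMap
) -> tuple[list[CaseReport], Counter[str]]:
    """Tag every reaction with its primary SOC.

    PTs absent from the map are tagged ``UNMAPPED`` and counted; they stay in
    the PT-level analysis but are excluded from SOC aggregation.
    """
    unmapped: Counter[str] = Counter()
    out: list[CaseReport] = []
    for case in cases:
        reactions = []
        for r in case.reactions:
            hit = meddra.lookup(r.pt)
            if hit is None:
                unmapped[r.pt] += 1
                reactions.append(Reaction(r.pt, UNMAPPED, UNMAPPED))
            else:
                reactions.append(Reaction(r.pt, hit[0], hit[1]))
        out.append(replace(case, reactions=reactions))
    if unmapped:
        logger.warning("%d reaction occurrences across %d PTs had no SOC mapping", sum(unmapped.values()), len(unmapped))
    return out, unmapped
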