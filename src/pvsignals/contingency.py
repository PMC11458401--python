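"""Drug-event 2x2 contingency tables at PT and SOC level.

For each event (a preferred term, or a system organ class after PT->SOC
aggregation) the four-grid counts target-drug reports against the background
corpus::

                         target event   all other events
    target-drug reports       a                b
    background reports        c                d

The default counting unit is the (report, PT) occurrence: a report listing
three PTs contributes three counting units. This is the convention under
which SOC-level counts can exceed the number of reports — as they do in real
spontaneous-report analyses where one report fans out over several events —
and it makes SOC counts the exact sum of their member-PT counts. Unique
report counting is available as an option.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass

from .preprocess import UNMAPPED, ScreenedDataset

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ContingencyTable:
    """The four-grid (a, b, c, d) for one event at one level."""

    event_id: str
    level: str  # "PT" or "SOC"
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError(f"negative cell in table for {self.event_id!r}")
        if self.level not in ("PT", "SOC"):
            raise ValueError(f"level must be PT or SOC, got {self.level!r}")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def cells(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)


@dataclass(frozen=True)
class CountingPolicy:
    """``unit="pair"`` counts (report, PT) occurrences; ``unit="report"``
    counts distinct reports. Fixed for a whole run."""

    unit: str = "pair"

    def __post_init__(self) -> None:
        if self.unit not in ("pair", "report"):
            raise ValueError(f"unit must be 'pair' or 'report', got {self.unit!r}")


def _pt_keys(case, unit: str) -> list[str]:
    pts = [r.pt for r in case.reactions]
    return sorted(set(pts)) if unit == "report" else pts


def _soc_keys(case, unit: str) -> list[str]:
    socs = [r.soc_name for r in case.reactions if r.soc_name not in (None, UNMAPPED)]
    return sorted(set(socs)) if unit == "report" else socs


def _count(cases, key_fn, unit: str) -> tuple[Counter, int]:
    counts: Counter[str] = Counter()
    total = 0
    for case in cases:
        keys = key_fn(case, unit)
        counts.update(keys)
        total += len(keys)
    return counts, total


def _build(data: ScreenedDataset, key_fn, level: str, policy: CountingPolicy) -> list[ContingencyTable]:
    if not data.target_reports:
        warnings.warn(f"no target reports; returning no {level}-level tables", stacklevel=3)
        return []
    tc, t_total = _count(data.target_reports, key_fn, policy.unit)
    bc, b_total = _count(data.background_reports, key_fn, policy.unit)
    if policy.unit == "report":
        # margins are report counts: a+b = target reports, c+d = background
        t_total = len(data.target_reports)
        b_total = len(data.background_reports)
    tables = []
    for event in sorted(tc):
        a = tc[event]
        c = bc.get(event, 0)
        tables.append(ContingencyTable(event_id=event, level=level, a=a, b=t_total - a, c=c, d=b_total - c))
    return tables


def build_pt_tables(data: ScreenedDataset, policy: CountingPolicy = CountingPolicy()) -> list[ContingencyTable]:
    """One table per PT observed in the target reports.

    Under the pair unit, a+b is the total number of target (report, PT)
    occurrences — identical across every table of the run — and c+d likewise
    for the background.
    """
    return _build(data, _pt_keys, "PT", policy)


def build_soc_tables(data: ScreenedDataset, policy: CountingPolicy = CountingPolicy()) -> list[ContingencyTable]:
    """One table per SOC observed in the target reports.

    Requires SOC-annotated reactions. Under the pair unit each PT occurrence
    contributes one count to its SOC, so a SOC's ``a`` is exactly the sum of
    its member PTs' ``a`` values; unmapped PTs are excluded (they are counted
    at annotation time).
    """
    n_unmapped = sum(
        1
        for case in list(data.target_reports) + list(data.background_reports)
        for r in case.reactions
        if r.soc_name in (None, UNMAPPED)
    )
    if n_unmapped:
        logger.info("SOC aggregation excluded %d unmapped PT occurrences", n_unmapped)
    return _build(data, _soc_keys, "SOC", policy)
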