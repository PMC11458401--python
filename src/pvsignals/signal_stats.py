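"""Disproportionality statistics and signal thresholds for 2x2 tables.

Four statistics are computed for every drug-event four-grid (a, b, c, d),
N = a+b+c+d:

ROR
    reporting odds ratio ``ad/bc`` with the Woolf 95% interval
    ``exp(ln ROR ± 1.96·sqrt(1/a + 1/b + 1/c + 1/d))``.
PRR
    proportional reporting ratio ``[a/(a+b)] / [c/(c+d)]`` with
    ``SE(ln PRR) = sqrt(1/a − 1/(a+b) + 1/c − 1/(c+d))``.
chi-square
    Pearson chi-square of the 2x2, with the Yates continuity correction by
    default: ``N·(|ad−bc| − N/2)² / [(a+b)(c+d)(a+c)(b+d)]``.
IC / IC025
    the BCPNN information component ``log2 P(x,y)/(P(x)P(y))`` under the
    Bate (1998) Dirichlet/Beta priors; IC025 here is the conventional
    ``E(IC) − 2·sqrt(V(IC))`` lower bound, not a posterior quantile.
EBGM / EBGM05
    the observed/expected ratio ``a·N / ((a+b)(a+c))`` (the relative
    reporting ratio that the empirical-Bayes geometric mean shrinks toward
    the null), with a Woolf-type lower interval limit
    ``exp(ln EBGM − 1.96·sqrt(1/a + 1/b + 1/c + 1/d))``. No gamma-Poisson
    hyperparameter fitting (full MGPS) is performed; run metadata records
    this choice.

A signal flag per statistic follows the conventional thresholds (a >= 3 with
interval lower limit > 1 for ROR and PRR; IC025 > 0; EBGM05 > 2), plus the
all-four intersection used to call a signal robust.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

from .contingency import ContingencyTable

_Z95 = 1.96
_LN2 = math.log(2.0)


class UndefinedScoreError(ValueError):
    """A statistic is undefined for the given cells without a correction."""


@dataclass(frozen=True)
class BcpnnPriors:
    """Prior constants of the BCPNN information component (Bate 1998).

    ``alpha1``/``beta1`` are the Beta priors of the two margins, ``gamma11``
    the joint-cell prior, and ``alpha``/``beta`` the corresponding prior
    sample sizes; the joint prior scale gamma is derived per table as
    ``gamma11·(N+alpha)(N+beta) / ((a+b+alpha1)(a+c+beta1))`` so that IC has
    zero prior expectation under independence.
    """

    alpha1: float = 1.0
    beta1: float = 1.0
    gamma11: float = 1.0
    alpha: float = 2.0
    beta: float = 2.0

    def __post_init__(self) -> None:
        if min(self.alpha1, self.beta1, self.gamma11, self.alpha, self.beta) <= 0:
            raise ValueError("all BCPNN prior constants must be strictly positive")


@dataclass(frozen=True)
class Thresholds:
    """Signal thresholds: ``a >= min_a`` with CI lower limit > 1 for ROR and
    PRR; ``IC025 > 0``; ``EBGM05 > 2``."""

    min_a: int = 3
    ror_ci_low_gt: float = 1.0
    prr_ci_low_gt: float = 1.0
    ic025_gt: float = 0.0
    ebgm05_gt: float = 2.0

    def __post_init__(self) -> None:
        if self.min_a < 1:
            raise ValueError("min_a must be >= 1")


@dataclass(frozen=True)
class SignalScores:
    a: int
    ror: float
    ror_ci95: tuple[float, float]
    prr: float
    prr_ci95: tuple[float, float]
    chi2: float
    ic: float
    ic025: float
    ebgm: float
    ebgm05: float


@dataclass(frozen=True)
class SignalDecision:
    pass_ror: bool
    pass_prr: bool
    pass_bcpnn: bool
    pass_ebgm: bool

    @property
    def pass_all(self) -> bool:
        return self.pass_ror and self.pass_prr and self.pass_bcpnn and self.pass_ebgm


def _corrected_cells(t: ContingencyTable, correction: str, *, require: tuple[str, ...]) -> tuple[float, float, float, float]:
    cells = dict(zip("abcd", (float(x) for x in t.cells())))
    if correction == "haldane":
        if min(cells.values()) == 0:
            cells = {k: v + 0.5 for k, v in cells.items()}
    elif correction == "none":
        for name in require:
            if cells[name] == 0:
                raise UndefinedScoreError(f"cell {name} is zero for event {t.event_id!r}; use the Haldane correction")
    else:
        raise ValueError(f"correction must be 'none' or 'haldane', got {correction!r}")
    return cells["a"], cells["b"], cells["c"], cells["d"]


def ror_score(t: ContingencyTable, correction: str = "haldane") -> tuple[float, tuple[float, float]]:
    """Reporting odds ratio with Woolf 95% CI.

    With ``correction="haldane"`` 0.5 is added to every cell, but only when
    some cell is zero; ``"none"`` raises on zero cells instead.
    """
    a, b, c, d = _corrected_cells(t, correction, require=("a", "b", "c", "d"))
    ror = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo, hi = math.exp(math.log(ror) - _Z95 * se), math.exp(math.log(ror) + _Z95 * se)
    return ror, (lo, hi)


def prr_score(t: ContingencyTable, correction: str = "haldane") -> tuple[float, tuple[float, float]]:
    """Proportional reporting ratio with its 95% CI."""
    a, b, c, d = _corrected_cells(t, correction, require=("a", "c"))
    if a + b == 0 or c + d == 0:
        raise UndefinedScoreError(f"zero margin for event {t.event_id!r}")
    prr = (a / (a + b)) / (c / (c + d))
    se = math.sqrt(1 / a - 1 / (a + b) + 1 / c - 1 / (c + d))
    lo, hi = math.exp(math.log(prr) - _Z95 * se), math.exp(math.log(prr) + _Z95 * se)
    return prr, (lo, hi)


def chi2_score(t: ContingencyTable, yates: bool = True) -> float:
    """Pearson chi-square of the four-grid, Yates-corrected by default.

    A table with a zero margin carries no association information: the
    statistic is reported as 0 with a warning rather than an error.
    """
    a, b, c, d = (float(x) for x in t.cells())
    n = a + b + c + d
    if n == 0:
        raise UndefinedScoreError("empty table")
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        warnings.warn(f"zero margin for event {t.event_id!r}; chi2 reported as 0", stacklevel=2)
        return 0.0
    diff = abs(a * d - b * c)
    if yates:
        diff = max(diff - n / 2, 0.0)
    return n * diff * diff / denom


def bcpnn_score(t: ContingencyTable, priors: BcpnnPriors = BcpnnPriors()) -> tuple[float, float]:
    """BCPNN information component: (E(IC), IC025 = E(IC) − 2·sqrt(V(IC))).

    The priors regularise every cell, so the score is finite on any
    non-empty table, zeros included.
    """
    a = float(t.a)
    n = float(t.n)
    if n == 0:
        raise UndefinedScoreError("empty table")
    ab = float(t.a + t.b)
    ac = float(t.a + t.c)
    p = priors
    gamma = p.gamma11 * (n + p.alpha) * (n + p.beta) / ((ab + p.alpha1) * (ac + p.beta1))
    e_ic = math.log2(
        (a + p.gamma11) * (n + p.alpha) * (n + p.beta) / ((n + gamma) * (ab + p.alpha1) * (ac + p.beta1))
    )
    v_ic = (
        (n - a + gamma - p.gamma11) / ((a + p.gamma11) * (1 + n + gamma))
        + (n - ab + p.alpha - p.alpha1) / ((ab + p.alpha1) * (1 + n + p.alpha))
        + (n - ac + p.beta - p.beta1) / ((ac + p.beta1) * (1 + n + p.beta))
    ) / (_LN2 ** 2)
    return e_ic, e_ic - 2.0 * math.sqrt(v_ic)


def ebgm_score(t: ContingencyTable) -> tuple[float, float]:
    """Observed/expected EBGM ``a·N/((a+b)(a+c))`` and its lower 95% limit.

    ``a = 0`` yields (0, 0); zero cells are Haldane-corrected for the
    standard error only, never for the point estimate.
    """
    a, b, c, d = (float(x) for x in t.cells())
    n = a + b + c + d
    if a + b == 0 or a + c == 0:
        raise UndefinedScoreError(f"zero margin for event {t.event_id!r}")
    if a == 0:
        return 0.0, 0.0
    ebgm = a * n / ((a + b) * (a + c))
    sa, sb, sc, sd = (x + 0.5 if min(a, b, c, d) == 0 else x for x in (a, b, c, d))
    se = math.sqrt(1 / sa + 1 / sb + 1 / sc + 1 / sd)
    return ebgm, math.exp(math.log(ebgm) - _Z95 * se)


def compute_scores(
    t: ContingencyTable,
    priors: BcpnnPriors = BcpnnPriors(),
    correction: str = "haldane",
    yates: bool = True,
) -> SignalScores:
    """All five statistics for one table."""
    ror, ror_ci = ror_score(t, correction)
    prr, prr_ci = prr_score(t, correction)
    chi2 = chi2_score(t, yates=yates)
    ic, ic025 = bcpnn_score(t, priors)
    ebgm, ebgm05 = ebgm_score(t)
    return SignalScores(
        a=t.a, ror=ror, ror_ci95=ror_ci, prr=prr, prr_ci95=prr_ci,
        chi2=chi2, ic=ic, ic025=ic025, ebgm=ebgm, ebgm05=ebgm05,
    )


def decide(s: SignalScores, th: Thresholds = Thresholds()) -> SignalDecision:
    """Apply the four signal thresholds to one set of scores."""
    count_ok = s.a >= th.min_a
    return SignalDecision(
        pass_ror=count_ok and s.ror_ci95[0] > th.ror_ci_low_gt,
        pass_prr=count_ok and s.prr_ci95[0] > th.prr_ci_low_gt,
        pass_bcpnn=s.ic025 > th.ic025_gt,
        pass_ebgm=s.ebgm05 > th.ebgm05_gt,
    )


@dataclass(frozen=True)
class ScoredRow:
    event_id: str
    level: str
    table: ContingencyTable
    scores: Optional[SignalScores]
    decision: Optional[SignalDecision]
    error: Optional[str] = None


def score_all(
    tables: Iterable[ContingencyTable],
    priors: BcpnnPriors = BcpnnPriors(),
    thresholds: Thresholds = Thresholds(),
    correction: str = "haldane",
    yates: bool = True,
) -> list[ScoredRow]:
    """Score every table and sort by EBGM descending, ties by event_id.

    Tables where a statistic is undefined come through as flagged rows (with
    the error message) rather than aborting the run; they sort last.
    """
    rows: list[ScoredRow] = []
    for t in tables:
        try:
            s = compute_scores(t, priors=priors, correction=correction, yates=yates)
            rows.append(ScoredRow(t.event_id, t.level, t, s, decide(s, thresholds)))
        except UndefinedScoreError as exc:
            rows.append(ScoredRow(t.event_id, t.level, t, None, None, error=str(exc)))
    rows.sort(key=lambda r: (-(r.scores.ebgm if r.scores else -math.inf), r.event_id))
    return rows


def scores_frame(rows: Iterable[ScoredRow]) -> pd.DataFrame:
    """Flatten scored rows to the standard signal-table layout."""
    records = []
    for r in rows:
        s, dec = r.scores, r.decision
        records.append(
            {
                "event_id": r.event_id,
                "level": r.level,
                "a": r.table.a,
                "b": r.table.b,
                "c": r.table.c,
                "d": r.table.d,
                "ror": s.ror if s else float("nan"),
                "ror_low": s.ror_ci95[0] if s else float("nan"),
                "ror_high": s.ror_ci95[1] if s else float("nan"),
                "prr": s.prr if s else float("nan"),
                "prr_low": s.prr_ci95[0] if s else float("nan"),
                "prr_high": s.prr_ci95[1] if s else float("nan"),
                "chi2": s.chi2 if s else float("nan"),
                "ic": s.ic if s else float("nan"),
                "ic025": s.ic025 if s else float("nan"),
                "ebgm": s.ebgm if s else float("nan"),
                "ebgm05": s.ebgm05 if s else float("nan"),
                "pass_ror": dec.pass_ror if dec else False,
                "pass_prr": dec.pass_prr if dec else False,
                "pass_bcpnn": dec.pass_bcpnn if dec else False,
                "pass_ebgm": dec.pass_ebgm if dec else False,
                "pass_all": dec.pass_all if dec else False,
            }
        )
    return pd.DataFrame.from_records(records)
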