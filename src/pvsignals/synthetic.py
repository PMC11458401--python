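"""Synthetic FAERS-shaped corpora with known ground truth.

The generator emulates the structure of a spontaneous-reporting quarter that
the rest of the package consumes: per-case drug records with role codes,
several reaction PTs per case, case versioning (duplicates), missing
demographics, and reporter/country/age/outcome strata whose default
proportions mirror a real capmatinib report corpus (about 49% female
reports, 54% consumer-reported, 63% from the US, 71% missing age). Signals
are planted multiplicatively: a target report draws catalog PT ``j`` with
probability ``min(1, background_prob_j x RR_j)``, so the planted relative
risk is exactly the estimand that disproportionality statistics target.

Every report draws at least one PT (rows that come up empty are redrawn), so
the per-report PT count is Poisson-like with mean ~2 under the default
catalog of 100 PTs at background probability 0.02, truncated at one.

All randomness flows from ``SimConfig.seed``: the same config produces
byte-identical tables.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .contingency import ContingencyTable
from .faers_io import RawQuarter

_AGE_BAND_RANGES = {
    "<18": (2, 17),
    "18-45": (18, 44),
    "45-65": (45, 64),
    "65-75": (65, 74),
    ">=75": (75, 95),
}

# stratum proportions of a real capmatinib report corpus (n=1,991):
# sex and reporter renormalised over their known categories, age over the
# 579 reports with known age, report years over 2020Q2-2023Q4
DEFAULT_DEMOGRAPHIC_PROBS: dict[str, dict] = {
    "sex": {"F": 0.554, "M": 0.446},
    "reporter": {"consumer": 0.5566, "physician": 0.3036, "pharmacist": 0.1398},
    "country": {"US": 0.625, "FR": 0.043, "JP": 0.021, "NL": 0.016, "OTHER": 0.295},
    "age_stratum": {"<18": 2 / 579, "18-45": 12 / 579, "45-65": 109 / 579, "65-75": 214 / 579, ">=75": 242 / 579},
    "year": {"2020": 0.1005, "2021": 0.3029, "2022": 0.3225, "2023": 0.2741},
}

DEFAULT_MISSING_RATES: dict[str, float] = {
    "age": 0.709,
    "sex": 0.109,
    "reporter": 0.037,
    "country": 0.0,
    "event_date": 0.3,
}

# per-report outcome-code probabilities (multi-label, need not sum to 1)
DEFAULT_OUTCOME_PROBS: dict[str, float] = {"DE": 0.2602, "HO": 0.1572, "DS": 0.0181, "LT": 0.0146}

_BACKGROUND_DRUGS = tuple(f"DRUG_{i:02d}" for i in range(1, 21))


def default_pt_catalog(
    n_pts: int = 100, n_socs: int = 20, background_prob: float = 0.02
) -> list[tuple[str, str, float]]:
    """A uniform catalog of ``n_pts`` PTs spread round-robin over ``n_socs``
    SOCs, each with the same background reporting probability."""
    return [(f"PT_{i:03d}", f"SOC_{i % n_socs + 1:02d}", background_prob) for i in range(1, n_pts + 1)]


@dataclass(frozen=True)
class SimConfig:
    """Generator parameters; the defaults define the simulated study.

    ``pt_catalog`` entries are ``(pt, soc, background_prob)``;
    ``planted_signals`` are ``(pt, relative_risk)`` pairs applied to target
    reports only. ``duplicate_rate`` is the probability that a case is
    re-emitted as a second, higher version of itself.
    """

    n_target_reports: int = 2000
    n_background_reports: int = 20000
    pt_catalog: Sequence[tuple[str, str, float]] = field(default_factory=default_pt_catalog)
    planted_signals: Sequence[tuple[str, float]] = ()
    duplicate_rate: float = 0.1
    missing_rates: dict = field(default_factory=lambda: dict(DEFAULT_MISSING_RATES))
    demographic_probs: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_DEMOGRAPHIC_PROBS.items()})
    outcome_probs: dict = field(default_factory=lambda: dict(DEFAULT_OUTCOME_PROBS))
    target_drug_names: Sequence[str] = ("TABRECTA", "CAPMATINIB")
    background_capmatinib_rate: float = 0.01  # non-suspect capmatinib mentions in background reports
    seed: int = 0

    def validate(self) -> None:
        if self.n_target_reports < 1 or self.n_background_reports < 0:
            raise ValueError("need at least one target report and a nonnegative background size")
        pts = [pt for pt, _, _ in self.pt_catalog]
        if len(pts) != len(set(pts)):
            raise ValueError("pt_catalog PTs must be unique")
        probs = np.array([p for _, _, p in self.pt_catalog], dtype=float)
        if not len(probs) or (probs < 0).any() or (probs > 1).any():
            raise ValueError("background probabilities must lie in [0, 1]")
        known = set(pts)
        for pt, rr in self.planted_signals:
            if pt not in known:
                raise ValueError(f"planted PT {pt!r} is not in the catalog")
            if rr < 0:
                raise ValueError("relative risks must be >= 0")
        if not (0 <= self.duplicate_rate <= 1):
            raise ValueError("duplicate_rate must be a probability")
        for fld, rate in self.missing_rates.items():
            if not (0 <= rate <= 1):
                raise ValueError(f"missing rate for {fld!r} must be a probability")
        for fld, cat in self.demographic_probs.items():
            total = sum(cat.values())
            if abs(total - 1.0) > 1e-6:
                raise ValueError(f"demographic probabilities for {fld!r} sum to {total}, not 1")
        target_probs = np.minimum(1.0, probs * self._rr_vector(pts))
        if target_probs.sum() == 0 and probs.sum() == 0:
            raise ValueError("infeasible config: all PT probabilities are zero")

    def _rr_vector(self, pts: Sequence[str]) -> np.ndarray:
        rr = {pt: r for pt, r in self.planted_signals}
        return np.array([rr.get(pt, 1.0) for pt in pts], dtype=float)


@dataclass
class SyntheticTruth:
    """Ground truth for one generated dataset.

    Sufficient to recompute every screening-log entry and every contingency
    table without running the pipeline: per-case exposure, per-pair true
    occurrence counts, the duplicate lineage and the missingness masks.
    """

    caseids: list[str]
    exposure: np.ndarray  # bool per unique case
    pair_counts: pd.DataFrame  # pt, soc, target_occurrences, background_occurrences
    duplicate_lineage: dict[str, list[int]]
    missing_masks: dict[str, np.ndarray]
    config: SimConfig

    @property
    def n_unique_cases(self) -> int:
        return len(self.caseids)

    @property
    def n_duplicates(self) -> int:
        return sum(len(v) - 1 for v in self.duplicate_lineage.values())


def _draw_categorical(rng: np.random.Generator, cat: dict, size: int) -> np.ndarray:
    keys = np.array(list(cat.keys()), dtype=object)
    p = np.array(list(cat.values()), dtype=float)
    return keys[rng.choice(len(keys), size=size, p=p / p.sum())]


_QUARTERS = [(y, q) for y in (2020, 2021, 2022, 2023) for q in (1, 2, 3, 4) if not (y == 2020 and q == 1)]


def _draw_fda_dates(rng: np.random.Generator, year_probs: dict, size: int) -> np.ndarray:
    """Receipt dates: year by configured probability, quarter uniform within
    the covered part of the year, day uniform within the quarter."""
    quarters = np.array([f"{y}Q{q}" for y, q in _QUARTERS])
    per_year = {str(y): sum(1 for yy, _ in _QUARTERS if yy == y) for y in (2020, 2021, 2022, 2023)}
    p = np.array([year_probs[str(y)] / per_year[str(y)] for y, _ in _QUARTERS], dtype=float)
    qi = rng.choice(len(quarters), size=size, p=p / p.sum())
    starts = pd.PeriodIndex(quarters, freq="Q").start_time
    lengths = (pd.PeriodIndex(quarters, freq="Q").end_time.normalize() - starts).days + 1
    offs = rng.integers(0, lengths.values[qi])
    return (starts.values[qi] + offs * np.timedelta64(1, "D")).astype("datetime64[ns]")


def generate(cfg: SimConfig) -> tuple[RawQuarter, SyntheticTruth]:
    """Generate one FAERS-shaped quarter plus its ground truth.

    Returns the in-memory tables (identical in layout to
    :func:`pvsignals.faers_io.read_quarter` output); use
    :func:`pvsignals.faers_io.write_quarter` to materialise files.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    nt, nb = cfg.n_target_reports, cfg.n_background_reports
    n = nt + nb
    exposure = np.zeros(n, dtype=bool)
    exposure[:nt] = True

    pts = np.array([pt for pt, _, _ in cfg.pt_catalog], dtype=object)
    socs = np.array([soc for _, soc, _ in cfg.pt_catalog], dtype=object)
    bg_probs = np.array([p for _, _, p in cfg.pt_catalog], dtype=float)
    target_probs = np.minimum(1.0, bg_probs * cfg._rr_vector([pt for pt, _, _ in cfg.pt_catalog]))
    prob_matrix = np.where(exposure[:, None], target_probs[None, :], bg_probs[None, :])

    pt_matrix = rng.random((n, len(pts))) < prob_matrix
    empty = ~pt_matrix.any(axis=1)
    while empty.any():  # every report carries at least one PT
        idx = np.flatnonzero(empty)
        pt_matrix[idx] = rng.random((len(idx), len(pts))) < prob_matrix[idx]
        empty[idx] = ~pt_matrix[idx].any(axis=1)

    caseids = np.array([str(100000000 + i) for i in range(n)], dtype=object)

    # demographics with per-field missingness
    dp = cfg.demographic_probs
    sex = _draw_categorical(rng, dp["sex"], n)
    reporter = _draw_categorical(rng, dp["reporter"], n)
    country = _draw_categorical(rng, dp["country"], n)
    stratum = _draw_categorical(rng, dp["age_stratum"], n)
    lo = np.array([_AGE_BAND_RANGES[s][0] for s in stratum])
    hi = np.array([_AGE_BAND_RANGES[s][1] for s in stratum])
    age = rng.integers(lo, hi + 1).astype(float)
    fda_date = _draw_fda_dates(rng, dp["year"], n)
    event_date = fda_date - rng.integers(0, 180, size=n) * np.timedelta64(1, "D")

    masks = {fld: rng.random(n) < cfg.missing_rates.get(fld, 0.0) for fld in ("age", "sex", "reporter", "country", "event_date")}
    sex = np.where(masks["sex"], "UNK", sex)
    reporter = np.where(masks["reporter"], "UNK", reporter)
    country = np.where(masks["country"], "", country)
    age = np.where(masks["age"], np.nan, age)
    event_date = np.where(masks["event_date"], np.datetime64("NaT"), event_date)

    # drug records, keyed by case index before version expansion
    tgt_name = np.array(cfg.target_drug_names, dtype=object)[rng.integers(0, len(cfg.target_drug_names), nt)]
    d_idx = [np.arange(nt)]
    d_name = [tgt_name]
    d_ai = [np.full(nt, "CAPMATINIB", dtype=object)]
    d_role = [np.full(nt, "PS", dtype=object)]

    def _ingredient(names: np.ndarray) -> np.ndarray:
        return np.array([s.replace("DRUG", "INGREDIENT") for s in names], dtype=object)

    bg_drugs = np.array(_BACKGROUND_DRUGS, dtype=object)
    bg_primary = bg_drugs[rng.integers(0, len(bg_drugs), nb)]
    d_idx.append(np.arange(nt, n))
    d_name.append(bg_primary)
    d_ai.append(_ingredient(bg_primary))
    d_role.append(np.full(nb, "PS", dtype=object))

    extras = rng.integers(0, 3, size=n)
    e_idx = np.repeat(np.arange(n), extras)
    e_name = bg_drugs[rng.integers(0, len(bg_drugs), len(e_idx))]
    d_idx.append(e_idx)
    d_name.append(e_name)
    d_ai.append(_ingredient(e_name))
    d_role.append(np.array(["SS", "C"], dtype=object)[rng.integers(0, 2, len(e_idx))])

    conc = np.flatnonzero(rng.random(nb) < cfg.background_capmatinib_rate) + nt
    if len(conc):  # capmatinib mentioned but not suspected: must stay background
        d_idx.append(conc)
        d_name.append(np.full(len(conc), "CAPMATINIB", dtype=object))
        d_ai.append(np.full(len(conc), "CAPMATINIB", dtype=object))
        d_role.append(np.full(len(conc), "C", dtype=object))

    drug_case = np.concatenate(d_idx)
    order = np.argsort(drug_case, kind="stable")
    drug_case = drug_case[order]
    drug_name = np.concatenate(d_name)[order]
    drug_ai = np.concatenate(d_ai)[order]
    drug_role = np.concatenate(d_role)[order]
    counts = np.bincount(drug_case, minlength=n)
    starts = np.cumsum(counts) - counts
    drug_seq = np.arange(len(drug_case)) - starts[drug_case] + 1

    reac_case, reac_pt_idx = np.nonzero(pt_matrix)
    reac_pt = pts[reac_pt_idx]

    oc_case, oc_code = [], []
    for code, p in cfg.outcome_probs.items():
        hit = np.flatnonzero(rng.random(n) < p)
        oc_case.append(hit)
        oc_code.append(np.full(len(hit), code, dtype=object))
    outc_case = np.concatenate(oc_case) if oc_case else np.array([], dtype=int)
    outc_code = np.concatenate(oc_code) if oc_code else np.array([], dtype=object)
    oorder = np.argsort(outc_case, kind="stable")
    outc_case, outc_code = outc_case[oorder], outc_code[oorder]

    # duplicate cases: re-emit the whole case as caseversion 2, a week later
    dup = rng.random(n) < cfg.duplicate_rate
    dup_idx = np.flatnonzero(dup)

    def _pid(idx: np.ndarray, version: int) -> np.ndarray:
        return np.array([f"{cid}{version}" for cid in caseids[idx]], dtype=object)

    all_idx = np.arange(n)
    demo_idx = np.concatenate([all_idx, dup_idx])
    demo_version = np.concatenate([np.ones(n, dtype=int), np.full(len(dup_idx), 2, dtype=int)])
    demo_fda = np.concatenate([fda_date, fda_date[dup_idx] + np.timedelta64(7, "D")])
    demo = pd.DataFrame(
        {
            "primaryid": np.concatenate([_pid(all_idx, 1), _pid(dup_idx, 2)]),
            "caseid": caseids[demo_idx],
            "caseversion": demo_version,
            "event_date": pd.to_datetime(np.concatenate([event_date, event_date[dup_idx]])),
            "age": np.concatenate([age, age[dup_idx]]),
            "sex": np.concatenate([sex, sex[dup_idx]]),
            "reporter": np.concatenate([reporter, reporter[dup_idx]]),
            "country": np.concatenate([country, country[dup_idx]]),
            "fda_date": pd.to_datetime(demo_fda),
        }
    )
    demo = demo.sort_values(["caseid", "caseversion"], kind="stable", ignore_index=True)

    def _child(case_idx: np.ndarray, cols: dict) -> pd.DataFrame:
        in_dup = np.isin(case_idx, dup_idx)
        pid = np.concatenate([_pid(case_idx, 1), _pid(case_idx[in_dup], 2)])
        out = {"primaryid": pid}
        for name, values in cols.items():
            out[name] = np.concatenate([values, values[in_dup]])
        df = pd.DataFrame(out)
        return df.sort_values("primaryid", kind="stable", ignore_index=True)

    drug = _child(drug_case, {"drug_seq": drug_seq, "drugname": drug_name, "prod_ai": drug_ai, "role_code": drug_role})
    reac = _child(reac_case, {"pt": reac_pt})
    outc = _child(outc_case, {"outcome_code": outc_code})
    raw = RawQuarter(demo=demo, drug=drug, reac=reac, outc=outc)

    pair_counts = pd.DataFrame(
        {
            "pt": pts,
            "soc": socs,
            "target_occurrences": pt_matrix[:nt].sum(axis=0).astype(int),
            "background_occurrences": pt_matrix[nt:].sum(axis=0).astype(int),
        }
    )
    truth = SyntheticTruth(
        caseids=list(caseids),
        exposure=exposure,
        pair_counts=pair_counts,
        duplicate_lineage={caseids[i]: [1, 2] if dup[i] else [1] for i in range(n)},
        missing_masks=masks,
        config=cfg,
    )
    return raw, truth


def truth_tables(truth: SyntheticTruth, level: str = "PT") -> list[ContingencyTable]:
    """Contingency tables computed directly from ground truth, bypassing the
    pipeline: the independent counting path used as an oracle.

    Pair-occurrence counting; only events observed in target reports yield a
    table, mirroring the pipeline's convention.
    """
    df = truth.pair_counts
    if level == "SOC":
        df = df.groupby("soc", as_index=False)[["target_occurrences", "background_occurrences"]].sum()
        df = df.rename(columns={"soc": "pt"})
    t_total = int(df["target_occurrences"].sum())
    b_total = int(df["background_occurrences"].sum())
    tables = []
    for row in df.sort_values("pt").itertuples(index=False):
        a = int(row.target_occurrences)
        if a == 0:
            continue
        c = int(row.background_occurrences)
        tables.append(ContingencyTable(event_id=row.pt, level=level, a=a, b=t_total - a, c=c, d=b_total - c))
    return tables


def meddra_map_frame(cfg: SimConfig) -> pd.DataFrame:
    """A synthetic PT->SOC mapping covering the catalog, in the CSV layout
    that :func:`pvsignals.faers_io.read_meddra_map` reads. The SOC names and
    codes are invented; no licensed terminology is reproduced."""
    soc_names = sorted({soc for _, soc, _ in cfg.pt_catalog})
    codes = {soc: f"{90000000 + i}" for i, soc in enumerate(soc_names, start=1)}
    return pd.DataFrame(
        {
            "pt": [pt for pt, _, _ in cfg.pt_catalog],
            "soc_name": [soc for _, soc, _ in cfg.pt_catalog],
            "soc_code": [codes[soc] for _, soc, _ in cfg.pt_catalog],
        }
    )
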