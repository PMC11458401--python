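"""Reading, writing and assembly of FAERS-style quarterly report tables.

FAERS distributes each quarter as a set of ``$``-delimited ASCII tables with
one row per entity: DEMO (one row per report version), DRUG (one row per drug
record), REAC (one row per reported MedDRA preferred term) and OUTC (one row
per outcome code). This module parses those tables (or a CSV equivalent used
for fixtures), normalises the typed columns, and joins the four tables into
per-report :class:`CaseReport` records. It also loads a user-supplied PT->SOC
mapping; MedDRA itself is licensed and is never bundled.
"""

from __future__ import annotations

import dataclasses
import datetime
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TABLE_ROLES = ("demo", "drug", "reac", "outc")

DEMO_COLUMNS = ("primaryid", "caseid", "caseversion", "event_date", "age", "sex", "reporter", "country", "fda_date")
DRUG_COLUMNS = ("primaryid", "drug_seq", "drugname", "prod_ai", "role_code")
REAC_COLUMNS = ("primaryid", "pt")
OUTC_COLUMNS = ("primaryid", "outcome_code")

_COLUMNS = {"demo": DEMO_COLUMNS, "drug": DRUG_COLUMNS, "reac": REAC_COLUMNS, "outc": OUTC_COLUMNS}

SEX_CODES = ("F", "M", "UNK")
REPORTER_CODES = ("consumer", "physician", "pharmacist", "other", "UNK")
ROLE_CODES = ("PS", "SS", "C", "I")
OUTCOME_CODES = ("DE", "LT", "HO", "DS", "CA", "RI", "OT")

_DELIMITERS = {"faers_dollar": "$", "csv": ","}


class FormatError(ValueError):
    """A table does not conform to the expected layout."""


class EmptyTableError(FormatError):
    """A table file contains no data rows."""


@dataclass
class RawQuarter:
    """The four quarterly tables, parsed and type-normalised.

    Dates are ``datetime64`` (NaT when unparseable), age is float years (NaN
    when unparseable), and enum-like columns are normalised strings with
    unknown values mapped to ``"UNK"``. Rows are never dropped during parsing.
    """

    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    outc: pd.DataFrame

    def tables(self) -> Mapping[str, pd.DataFrame]:
        return {"demo": self.demo, "drug": self.drug, "reac": self.reac, "outc": self.outc}


@dataclass(frozen=True, slots=True)
class DrugRecord:
    drugname: str
    prod_ai: str
    role_code: str


@dataclass(frozen=True, slots=True)
class Reaction:
    """A reported preferred term, optionally annotated with its primary SOC."""

    pt: str
    soc_name: Optional[str] = None
    soc_code: Optional[str] = None


@dataclass(slots=True)
class CaseReport:
    """One safety report: identity, demographics, drug records and reactions."""

    caseid: str
    primaryid: str
    caseversion: int
    event_date: Optional[datetime.date]
    age: Optional[float]
    sex: str
    reporter: str
    country: str
    fda_date: Optional[datetime.date]
    drugs: list[DrugRecord] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)
    outcomes: frozenset[str] = field(default_factory=frozenset)


@dataclass
class AssemblyLog:
    """Row-accounting for :func:`assemble_cases`.

    Conservation: input reaction rows = reactions kept + orphans + collapsed
    duplicates.
    """

    n_cases: int = 0
    orphan_drug_rows: int = 0
    orphan_reac_rows: int = 0
    orphan_outc_rows: int = 0
    collapsed_reactions: int = 0
    no_reaction_reports: int = 0


def _read_table(path: str | Path, role: str, delimiter: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"{role} table not found: {path}")
    df = pd.read_csv(
        path,
        sep=delimiter,
        dtype=str,
        keep_default_na=False,
        encoding="utf-8",
        encoding_errors="replace",
        engine="python" if delimiter == "$" else "c",
    )
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in _COLUMNS[role] if c not in df.columns]
    if missing:
        raise FormatError(f"{role} table {path} is missing mandatory column(s): {', '.join(missing)}")
    if len(df) == 0:
        raise EmptyTableError(f"{role} table {path} has a header but no data rows")
    return df.loc[:, list(_COLUMNS[role])]


def _parse_dates(series: pd.Series) -> pd.Series:
    """Parse FAERS-style YYYYMMDD dates (ISO accepted); failures become NaT."""
    s = series.str.strip()
    out = pd.to_datetime(s, format="%Y%m%d", errors="coerce")
    iso = pd.to_datetime(s, format="%Y-%m-%d", errors="coerce")
    return out.fillna(iso)


def _normalise_enum(series: pd.Series, valid: Iterable[str], *, casefold: bool = False) -> pd.Series:
    s = series.str.strip()
    s = s.str.lower() if casefold else s.str.upper()
    return s.where(s.isin(tuple(valid)), "UNK")


def read_quarter(paths: Mapping[str, str | Path], dialect: str = "faers_dollar") -> RawQuarter:
    """Read one quarter's DEMO/DRUG/REAC/OUTC tables.

    Parameters
    ----------
    paths
        Mapping with keys ``demo``, ``drug``, ``reac``, ``outc`` giving the
        file path of each table.
    dialect
        ``"faers_dollar"`` for the ``$``-delimited ASCII layout, ``"csv"``
        for comma-separated fixtures.

    Unparseable dates and ages become missing values; rows are never dropped
    here. Raises :class:`FormatError` when a mandatory column is absent and
    :class:`EmptyTableError` for a header-only file.
    """
    if dialect not in _DELIMITERS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {sorted(_DELIMITERS)}")
    delim = _DELIMITERS[dialect]
    missing_roles = [r for r in TABLE_ROLES if r not in paths]
    if missing_roles:
        raise ValueError(f"paths must provide every table role; missing {missing_roles}")

    demo = _read_table(paths["demo"], "demo", delim)
    drug = _read_table(paths["drug"], "drug", delim)
    reac = _read_table(paths["reac"], "reac", delim)
    outc = _read_table(paths["outc"], "outc", delim)

    demo["caseversion"] = (
        pd.to_numeric(demo["caseversion"].str.strip(), errors="coerce").fillna(1).astype(int).clip(lower=1)
    )
    demo["event_date"] = _parse_dates(demo["event_date"])
    demo["fda_date"] = _parse_dates(demo["fda_date"])
    demo["age"] = pd.to_numeric(demo["age"].str.strip(), errors="coerce")
    demo["sex"] = _normalise_enum(demo["sex"], SEX_CODES)
    demo["reporter"] = _normalise_enum(demo["reporter"], REPORTER_CODES[:-1], casefold=True)
    demo["country"] = demo["country"].str.strip()

    drug["drug_seq"] = pd.to_numeric(drug["drug_seq"].str.strip(), errors="coerce").fillna(1).astype(int)
    drug["drugname"] = drug["drugname"].str.strip()
    drug["prod_ai"] = drug["prod_ai"].str.strip()
    drug["role_code"] = _normalise_enum(drug["role_code"], ROLE_CODES)

    reac["pt"] = reac["pt"].str.strip()
    outc["outcome_code"] = _normalise_enum(outc["outcome_code"], OUTCOME_CODES)

    for role, df in (("demo", demo), ("drug", drug), ("reac", reac), ("outc", outc)):
        logger.info("read %d %s rows", len(df), role)
    return RawQuarter(demo=demo, drug=drug, reac=reac, outc=outc)


def _format_date(value) -> str:
    if pd.isna(value):
        return ""
    return pd.Timestamp(value).strftime("%Y%m%d")


def _format_age(value) -> str:
    if pd.isna(value):
        return ""
    value = float(value)
    return str(int(value)) if value.is_integer() else repr(value)


def write_quarter(raw: RawQuarter, out_dir: str | Path, dialect: str = "faers_dollar") -> dict[str, Path]:
    """Write a :class:`RawQuarter` back to per-table files.

    Serialisation is canonical (dates as YYYYMMDD, missing values as empty
    fields), so reading a written quarter reproduces it field-for-field and a
    second write is byte-identical.
    """
    if dialect not in _DELIMITERS:
        raise ValueError(f"unknown dialect {dialect!r}")
    delim = _DELIMITERS[dialect]
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ext = "txt" if dialect == "faers_dollar" else "csv"

    paths: dict[str, Path] = {}
    for role, df in raw.tables().items():
        df = df.copy()
        if role == "demo":
            df["event_date"] = df["event_date"].map(_format_date)
            df["fda_date"] = df["fda_date"].map(_format_date)
            df["age"] = df["age"].map(_format_age)
        path = out_dir / f"{role}.{ext}"
        df.to_csv(path, sep=delim, index=False, lineterminator="\n")
        paths[role] = path
    return paths


def _date_or_none(value) -> Optional[datetime.date]:
    return None if pd.isna(value) else pd.Timestamp(value).date()


def assemble_cases(raw: RawQuarter) -> tuple[list[CaseReport], AssemblyLog]:
    """Join the four tables into one :class:`CaseReport` per primaryid.

    Drug, reaction and outcome rows whose primaryid has no DEMO row are
    orphans: they are excluded and counted. Duplicate (primaryid, pt)
    reaction rows collapse to one occurrence. Reports left with zero
    reactions are excluded and counted — a spontaneous report without a
    reported event carries no signal information.
    """
    log = AssemblyLog()
    known = set(raw.demo["primaryid"])

    def _split_orphans(df: pd.DataFrame) -> tuple[pd.DataFrame, int]:
        ok = df["primaryid"].isin(known)
        return df.loc[ok], int((~ok).sum())

    drug, log.orphan_drug_rows = _split_orphans(raw.drug)
    reac, log.orphan_reac_rows = _split_orphans(raw.reac)
    outc, log.orphan_outc_rows = _split_orphans(raw.outc)

    n_reac_before = len(reac)
    reac = reac.drop_duplicates(subset=["primaryid", "pt"])
    log.collapsed_reactions = n_reac_before - len(reac)
    if log.collapsed_reactions:
        logger.warning("collapsed %d duplicate (primaryid, pt) reaction rows", log.collapsed_reactions)

    drugs_by_id: dict[str, list[DrugRecord]] = {}
    for pid, name, ai, role in zip(drug["primaryid"], drug["drugname"], drug["prod_ai"], drug["role_code"]):
        drugs_by_id.setdefault(pid, []).append(DrugRecord(name, ai, role))
    reacs_by_id: dict[str, list[Reaction]] = {}
    for pid, pt in zip(reac["primaryid"], reac["pt"]):
        reacs_by_id.setdefault(pid, []).append(Reaction(pt))
    outc_by_id: dict[str, set[str]] = {}
    for pid, code in zip(outc["primaryid"], outc["outcome_code"]):
        outc_by_id.setdefault(pid, set()).add(code)

    cases: list[CaseReport] = []
    demo = raw.demo
    if demo["primaryid"].duplicated().any():
        # keep last occurrence per primaryid; versioned duplicates across
        # caseids are the deduplication stage's concern, not assembly's
        demo = demo.drop_duplicates(subset="primaryid", keep="last")
    for row in demo.itertuples(index=False):
        reactions = reacs_by_id.get(row.primaryid)
        if not reactions:
            log.no_reaction_reports += 1
            continue
        cases.append(
            CaseReport(
                caseid=row.caseid,
                primaryid=row.primaryid,
                caseversion=int(row.caseversion),
                event_date=_date_or_none(row.event_date),
                age=None if pd.isna(row.age) else float(row.age),
                sex=row.sex,
                reporter=row.reporter,
                country=row.country,
                fda_date=_date_or_none(row.fda_date),
                drugs=drugs_by_id.get(row.primaryid, []),
                reactions=reactions,
                outcomes=frozenset(outc_by_id.get(row.primaryid, ())),
            )
        )
    log.n_cases = len(cases)
    if log.no_reaction_reports:
        logger.warning("excluded %d reports with no reaction rows", log.no_reaction_reports)
    return cases, log


def normalise_pt(pt: str) -> str:
    """Whitespace-normalised, case-folded PT key used for map lookups."""
    return " ".join(pt.split()).casefold()


class MeddraMap:
    """PT -> primary (SOC name, SOC code) lookup.

    The mapping is a function: each PT resolves to exactly one primary SOC.
    Lookups are case-insensitive after whitespace normalisation.
    """

    def __init__(self, entries: Mapping[str, tuple[str, str]]):
        self._entries = {normalise_pt(pt): (soc_name, soc_code) for pt, (soc_name, soc_code) in entries.items()}

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, pt: str) -> bool:
        return normalise_pt(pt) in self._entries

    def lookup(self, pt: str) -> Optional[tuple[str, str]]:
        return self._entries.get(normalise_pt(pt))

    def soc_codes(self) -> set[str]:
        return {code for _, code in self._entries.values()}


def read_meddra_map(path: str | Path) -> MeddraMap:
    """Load a PT->SOC mapping CSV with columns ``pt, soc_name, soc_code``.

    A PT that appears twice with conflicting SOCs is a hard error (the
    mapping must be a function); consistent repeats collapse silently.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in ("pt", "soc_name", "soc_code") if c not in df.columns]
    if missing:
        raise FormatError(f"PT->SOC map {path} is missing column(s): {', '.join(missing)}")
    if len(df) == 0:
        raise EmptyTableError(f"PT->SOC map {path} has no entries")

    entries: dict[str, tuple[str, str]] = {}
    conflicts: Counter[str] = Counter()
    for pt, soc_name, soc_code in zip(df["pt"], df["soc_name"], df["soc_code"]):
        key = normalise_pt(pt)
        value = (soc_name.strip(), soc_code.strip())
        if key in entries and entries[key] != value:
            conflicts[pt.strip()] += 1
        entries.setdefault(key, value)
    if conflicts:
        offenders = ", ".join(sorted(conflicts))
        raise FormatError(f"PT->SOC map {path} maps PT(s) to more than one SOC: {offenders}")
    return MeddraMap({pt: value for pt, value in entries.items()})
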