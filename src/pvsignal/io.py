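"""Readers for FAERS-style quarterly ASCII tables.

FAERS distributes each quarter as ``$``-delimited latin-1 text with a header
row and no quoting.  The four tables consumed here are DEMO (one row per
report version), DRUG (one row per drug per report), REAC (one row per
reaction preferred term) and THER (therapy dates, keyed to DRUG rows by
``dsg_drug_seq``).  A case (``caseid``) may appear as several report
versions (``caseversion`` / ``primaryid``); analysis operates on one
deduplicated row per case — the latest version.

Because the format has no quoting or escaping, rows are validated by raw
field count against the header; rows with the wrong count are dropped and
counted (``read_counters``), as are DRUG/REAC/THER rows whose ``primaryid``
has no DEMO match.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import pandas as pd

from .errors import InputFormatError

logger = logging.getLogger(__name__)

__all__ = [
    "EventDefinition",
    "DrugExposure",
    "Report",
    "ReportSet",
    "read_quarter",
    "find_quarter_files",
    "deduplicate",
    "flag_event_cases",
    "normalize_drug_names",
    "case_table",
    "exposure_matrix",
    "suspect_pairs",
    "iter_reports",
    "load_term_list",
    "load_synonym_map",
    "SUSPECT_ROLES",
]

REQUIRED_COLUMNS = {
    "demo": ("primaryid", "caseid", "caseversion", "event_dt", "sex",
             "age", "age_cod", "wt", "occp_cod"),
    "drug": ("primaryid", "caseid", "drug_seq", "drugname", "role_cod"),
    "reac": ("primaryid", "caseid", "pt"),
    "ther": ("primaryid", "caseid", "dsg_drug_seq", "start_dt"),
}

#: Drug roles counted as exposure by default: primary and secondary suspect.
SUSPECT_ROLES = ("PS", "SS")

_AGE_UNIT_YEARS = {"YR": 1.0, "YEAR": 1.0, "DEC": 10.0, "MON": 1.0 / 12.0,
                   "WK": 1.0 / 52.1775, "DY": 1.0 / 365.25,
                   "HR": 1.0 / 8765.8}

_SEX_LEVELS = {"F": "female", "M": "male"}
_OCCP_LEVELS = {"CN": "consumer", "LW": "lawyer", "MD": "physician",
                "OT": "other_health_professional", "PH": "pharmacist"}


@dataclass(frozen=True)
class EventDefinition:
    """A named adverse-event group defined by a flat preferred-term list.

    Stands in for a MedDRA SMQ narrow query; matching is case-insensitive
    after whitespace trimming.
    """

    name: str
    preferred_terms: frozenset[str]

    def __post_init__(self) -> None:
        terms = frozenset(t.strip().lower() for t in self.preferred_terms
                          if t.strip())
        if not terms:
            raise InputFormatError(
                f"event definition {self.name!r} has no preferred terms")
        object.__setattr__(self, "preferred_terms", terms)

    @classmethod
    def from_file(cls, name: str, path: str | Path) -> "EventDefinition":
        with open(path, encoding="utf-8") as fh:
            terms = [line.strip() for line in fh if line.strip()]
        return cls(name, frozenset(terms))


def load_term_list(name: str, path: str | Path) -> EventDefinition:
    return EventDefinition.from_file(name, path)


@dataclass(frozen=True)
class DrugExposure:
    drug_name: str
    role_code: str
    therapy_start_date: pd.Timestamp | None = None


@dataclass(frozen=True)
class Report:
    """One deduplicated individual case safety report."""

    case_id: str
    report_id: str
    sex: str
    age_years: float | None
    weight_kg: float | None
    reporter_occupation: str
    drugs: tuple[DrugExposure, ...]
    reactions: tuple[str, ...]
    event_date: pd.Timestamp | None


@dataclass
class ReportSet:
    """Columnar container for a set of reports (one DEMO row per version)."""

    demo: pd.DataFrame
    drugs: pd.DataFrame
    reactions: pd.DataFrame
    log: dict = field(default_factory=dict)

    @property
    def n_reports(self) -> int:
        return len(self.demo)

    @property
    def n_cases(self) -> int:
        return self.demo["caseid"].nunique()


def _read_table(path: Path, table: str) -> tuple[pd.DataFrame, int]:
    """Read one $-delimited table; drop and count rows with a bad field count."""
    if not path.exists():
        raise InputFormatError(f"{table.upper()} file not found: {path}")
    with open(path, encoding="latin-1", newline="") as fh:
        header_line = fh.readline()
        if not header_line.strip():
            raise InputFormatError(f"{table.upper()} file is empty: {path}")
        header = [h.strip().lower() for h in header_line.rstrip("\r\n").split("$")]
        missing = set(REQUIRED_COLUMNS[table]) - set(header)
        if missing:
            raise InputFormatError(
                f"{table.upper()} {path}: missing columns {sorted(missing)}")
        n_fields = len(header)
        rows, malformed = [], 0
        for line in fh:
            line = line.rstrip("\r\n")
            if not line:
                continue
            fields = line.split("$")
            if len(fields) != n_fields:
                malformed += 1
                continue
            rows.append(fields)
    df = pd.DataFrame(rows, columns=header, dtype=object)
    if malformed:
        logger.warning("%s %s: dropped %d malformed row(s)",
                       table.upper(), path.name, malformed)
    return df, malformed


def _parse_age_years(age: pd.Series, age_cod: pd.Series) -> pd.Series:
    value = pd.to_numeric(age, errors="coerce")
    unit = age_cod.fillna("").str.strip().str.upper().replace("", "YR")
    factor = unit.map(_AGE_UNIT_YEARS)
    years = value * factor
    return years.where(years >= 0)


def parse_faers_dates(raw: pd.Series) -> tuple[pd.Series, pd.Series]:
    """Parse YYYYMMDD / YYYYMM / YYYY integer dates.

    Returns (timestamps, precision) where precision is one of
    ``day``/``month``/``year``/``missing``.  Month-precision dates resolve to
    the first of the month; year-precision dates carry a timestamp too but
    are excluded from onset arithmetic by their precision flag.
    """
    s = raw.fillna("").astype(str).str.strip()
    s = s.str.replace(r"\.0$", "", regex=True)
    n = s.str.len()
    digits = s.str.fullmatch(r"\d+").fillna(False)
    prec = pd.Series("missing", index=s.index, dtype=object)
    prec[digits & (n == 8)] = "day"
    prec[digits & (n == 6)] = "month"
    prec[digits & (n == 4)] = "year"
    padded = s.where(~(prec == "month"), s + "01")
    padded = padded.where(~(prec == "year"), s + "0101")
    dates = pd.to_datetime(padded.where(prec != "missing"),
                           format="%Y%m%d", errors="coerce")
    prec[dates.isna()] = "missing"
    return dates, prec


def find_quarter_files(directory: str | Path) -> dict[str, list[Path]]:
    """Locate DEMO/DRUG/REAC/THER files (any quarters) in a directory."""
    directory = Path(directory)
    out: dict[str, list[Path]] = {}
    for table in ("demo", "drug", "reac", "ther"):
        out[table] = sorted(directory.glob(f"{table.upper()}*.txt"))
    return out


def read_quarter(paths: str | Path | Mapping[str, Path | Sequence[Path]]
                 ) -> ReportSet:
    """Read and join one or more quarters of DEMO/DRUG/REAC/THER files.

    ``paths`` is a directory (files found by FAERS naming convention) or a
    mapping ``{"demo": path_or_list, ...}``.  DRUG/REAC/THER rows whose
    ``primaryid`` is absent from DEMO are dropped with a logged count.
    """
    if isinstance(paths, (str, Path)):
        paths = find_quarter_files(paths)
    counters: dict[str, int] = {}
    frames: dict[str, pd.DataFrame] = {}
    for table in ("demo", "drug", "reac", "ther"):
        entry = paths.get(table)
        if entry is None or (isinstance(entry, (list, tuple)) and not entry):
            raise InputFormatError(f"no {table.upper()} file supplied")
        files = [Path(entry)] if isinstance(entry, (str, Path)) else \
            [Path(p) for p in entry]
        parts, malformed = [], 0
        for p in files:
            df, bad = _read_table(p, table)
            parts.append(df)
            malformed += bad
        frames[table] = pd.concat(parts, ignore_index=True)
        counters[f"malformed_{table}"] = malformed
    demo = frames["demo"]
    if demo.empty:
        raise InputFormatError("DEMO table contains no data rows")

    demo = demo.copy()
    demo["caseversion"] = pd.to_numeric(
        demo["caseversion"], errors="coerce").fillna(0).astype(int)
    demo["age_years"] = _parse_age_years(demo["age"], demo["age_cod"])
    demo["weight_kg"] = pd.to_numeric(demo["wt"], errors="coerce")
    demo["event_date"], demo["event_date_prec"] = \
        parse_faers_dates(demo["event_dt"])
    known = demo["primaryid"]

    drugs = frames["drug"].copy()
    orphan = ~drugs["primaryid"].isin(known)
    counters["orphan_drug"] = int(orphan.sum())
    drugs = drugs[~orphan].reset_index(drop=True)
    drugs["drugname"] = drugs["drugname"].fillna("").str.strip()
    drugs = drugs[drugs["drugname"] != ""].reset_index(drop=True)

    ther = frames["ther"].copy()
    orphan = ~ther["primaryid"].isin(known)
    counters["orphan_ther"] = int(orphan.sum())
    ther = ther[~orphan]
    ther = ther.rename(columns={"dsg_drug_seq": "drug_seq"})
    ther["start_date"], ther["start_date_prec"] = \
        parse_faers_dates(ther["start_dt"])
    drugs = drugs.merge(
        ther[["primaryid", "drug_seq", "start_date", "start_date_prec"]],
        on=["primaryid", "drug_seq"], how="left")
    drugs["start_date_prec"] = drugs["start_date_prec"].fillna("missing")

    reac = frames["reac"].copy()
    orphan = ~reac["primaryid"].isin(known)
    counters["orphan_reac"] = int(orphan.sum())
    reac = reac[~orphan].reset_index(drop=True)
    reac["pt_norm"] = reac["pt"].fillna("").str.strip().str.lower()

    counters["reports_read"] = len(demo)
    for k, v in counters.items():
        if v and k.startswith(("orphan", "malformed")):
            logger.warning("read_quarter: %s = %d", k, v)
    return ReportSet(demo=demo, drugs=drugs, reactions=reac, log=counters)


def deduplicate(reports: ReportSet) -> ReportSet:
    """Keep, per caseid, the report version with the greatest
    (caseversion, primaryid) — the latest submitted version.  Idempotent."""
    demo = reports.demo.sort_values(
        ["caseid", "caseversion", "primaryid"], kind="mergesort")
    survivors = demo.drop_duplicates("caseid", keep="last")
    removed = len(demo) - len(survivors)
    keep_pid = survivors["primaryid"]
    log = dict(reports.log)
    log["duplicates_removed"] = removed + log.get("duplicates_removed", 0)
    log["cases_after_dedup"] = len(survivors)
    return ReportSet(
        demo=survivors.reset_index(drop=True),
        drugs=reports.drugs[reports.drugs["primaryid"].isin(keep_pid)]
        .reset_index(drop=True),
        reactions=reports.reactions[
            reports.reactions["primaryid"].isin(keep_pid)]
        .reset_index(drop=True),
        log=log,
    )


def flag_event_cases(reports: ReportSet, event: EventDefinition) -> pd.Series:
    """Boolean per-case flag: any reaction term in the event's term list.

    Returns a Series indexed by caseid covering every case in the set;
    independent of reaction ordering, and a case can be flagged for several
    event definitions independently.
    """
    hits = reports.reactions[
        reports.reactions["pt_norm"].isin(event.preferred_terms)]
    flagged = set(hits["caseid"])
    caseids = reports.demo["caseid"].drop_duplicates()
    return pd.Series(caseids.isin(flagged).to_numpy(),
                     index=pd.Index(caseids, name="caseid"),
                     name=event.name)


def normalize_drug_names(reports: ReportSet,
                         synonym_map: Mapping[str, str] | None = None
                         ) -> ReportSet:
    """Lowercase/trim drug names and map through a synonym table (idempotent)."""
    if synonym_map:
        table = {k.strip().lower(): v.strip().lower()
                 for k, v in synonym_map.items()}
        if len(table) != len(synonym_map):
            raise InputFormatError(
                "synonym map keys collide after lowercasing")
    else:
        table = {}
    drugs = reports.drugs.copy()
    names = drugs["drugname"].str.strip().str.lower()
    if table:
        names = names.map(lambda s: table.get(s, s))
    drugs["drugname"] = names
    return ReportSet(demo=reports.demo, drugs=drugs,
                     reactions=reports.reactions, log=dict(reports.log))


def case_table(reports: ReportSet) -> pd.DataFrame:
    """One row per case (call after :func:`deduplicate`): demographics with
    enumerated sex/occupation levels, parsed age in years, event date."""
    demo = reports.demo
    out = pd.DataFrame({
        "caseid": demo["caseid"],
        "sex": demo["sex"].fillna("").str.strip().str.upper()
        .map(_SEX_LEVELS).fillna("missing"),
        "age_years": demo["age_years"],
        "weight_kg": demo["weight_kg"],
        "occupation": demo["occp_cod"].fillna("").str.strip().str.upper()
        .map(_OCCP_LEVELS).fillna("missing"),
        "event_date": demo["event_date"],
        "event_date_prec": demo["event_date_prec"],
    })
    return out.set_index("caseid")


def suspect_pairs(reports: ReportSet,
                  roles: Sequence[str] = SUSPECT_ROLES) -> pd.DataFrame:
    """Unique (caseid, drugname) pairs under the configured exposure roles."""
    d = reports.drugs
    mask = d["role_cod"].fillna("").str.strip().str.upper().isin(
        [r.upper() for r in roles])
    return d.loc[mask, ["caseid", "drugname"]].drop_duplicates() \
        .reset_index(drop=True)


def exposure_matrix(reports: ReportSet, drugs: Sequence[str],
                    roles: Sequence[str] = SUSPECT_ROLES) -> pd.DataFrame:
    """Boolean case x drug exposure indicators for the listed drugs."""
    pairs = suspect_pairs(reports, roles)
    caseids = pd.Index(reports.demo["caseid"].drop_duplicates(),
                       name="caseid")
    out = pd.DataFrame(False, index=caseids, columns=list(drugs))
    for name in drugs:
        exposed = pairs.loc[pairs["drugname"] == name, "caseid"]
        out.loc[out.index.isin(exposed), name] = True
    return out


def iter_reports(reports: ReportSet) -> Iterator[Report]:
    """Materialise :class:`Report` objects (convenience for small data)."""
    drugs_by_pid = {pid: grp for pid, grp in reports.drugs.groupby("primaryid")}
    reac_by_pid = {pid: grp for pid, grp in
                   reports.reactions.groupby("primaryid")}
    ct = case_table(reports)
    for row in reports.demo.itertuples(index=False):
        pid = row.primaryid
        exposures = []
        for d in drugs_by_pid.get(pid, pd.DataFrame()).itertuples(index=False):
            start = d.start_date if pd.notna(d.start_date) else None
            exposures.append(DrugExposure(d.drugname, d.role_cod, start))
        reactions = tuple(reac_by_pid[pid]["pt"]) if pid in reac_by_pid else ()
        c = ct.loc[row.caseid]
        yield Report(
            case_id=str(row.caseid), report_id=str(pid),
            sex=c["sex"],
            age_years=None if pd.isna(c["age_years"]) else float(c["age_years"]),
            weight_kg=None if pd.isna(c["weight_kg"]) else float(c["weight_kg"]),
            reporter_occupation=c["occupation"],
            drugs=tuple(exposures), reactions=reactions,
            event_date=c["event_date"] if pd.notna(c["event_date"]) else None,
        )


def load_synonym_map(path: str | Path) -> dict[str, str]:
    """Two-column delimited text (tab, ``$`` or comma): verbatim -> preferred."""
    out: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            for sep in ("\t", "$", ","):
                if sep in line:
                    key, value = line.split(sep, 1)
                    break
            else:
                raise InputFormatError(
                    f"synonym map line has no delimiter: {line!r}")
            out[key.strip()] = value.strip()
    return out
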