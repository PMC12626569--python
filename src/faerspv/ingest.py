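"""Reading FAERS-style quarterly ASCII tables and case deduplication.

FAERS quarterly extracts are ``$``-delimited text tables (DEMO, DRUG, REAC,
THER, OUTC, RPSR), one header line followed by one row per record.  A single
safety report is keyed by PRIMARYID; follow-up versions of the same case share
a CASEID.  The FDA-recommended deduplication keeps, for each CASEID, the row
with the latest FDA_DT, breaking ties by the highest PRIMARYID.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

TABLE_NAMES = ("demo", "drug", "reac", "ther", "outc", "rpsr")

#: FAERS age-unit codes -> multiplier converting AGE to years.
AGE_UNIT_TO_YEARS = {
    "DEC": 10.0,
    "YR": 1.0,
    "MON": 1.0 / 12.0,
    "WK": 1.0 / 52.0,
    "DY": 1.0 / 365.25,
    "HR": 1.0 / 8766.0,
}

OUTCOME_CODES = ("DE", "LT", "HO", "DS", "CA", "RI", "OT")


# ---------------------------------------------------------------------------
# Partial dates
# ---------------------------------------------------------------------------

_DAYS_IN_MONTH = (31, 29, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31)


def _calendar_valid(year: int, month: int, day: int) -> bool:
    if not (1 <= month <= 12 and 1 <= day <= 31):
        return False
    if day > _DAYS_IN_MONTH[month - 1]:
        return False
    if month == 2 and day == 29:
        leap = year % 4 == 0 and (year % 100 != 0 or year % 400 == 0)
        return leap
    return True


@dataclass(frozen=True)
class PartialDate:
    """A possibly incomplete date as reported in FAERS date fields.

    ``precision`` is one of ``day``, ``month``, ``year`` or ``invalid``.
    Arithmetic (day differences) is only meaningful at day precision.
    """

    year: int | None = None
    month: int | None = None
    day: int | None = None
    precision: str = "invalid"

    @property
    def sort_key(self) -> tuple[int, int, int]:
        """Ordering key; absent components sort first (zero-filled)."""
        return (self.year or 0, self.month or 0, self.day or 0)

    def to_timestamp(self) -> pd.Timestamp:
        if self.precision != "day":
            raise ValueError(f"not a day-precision date: {self!r}")
        return pd.Timestamp(year=self.year, month=self.month, day=self.day)

    def __str__(self) -> str:  # round-trips through parse_date
        if self.precision == "day":
            return f"{self.year:04d}{self.month:02d}{self.day:02d}"
        if self.precision == "month":
            return f"{self.year:04d}{self.month:02d}"
        if self.precision == "year":
            return f"{self.year:04d}"
        return ""


INVALID_DATE = PartialDate()


def parse_date(raw: str | None) -> PartialDate:
    """Parse a FAERS date string (YYYYMMDD / YYYYMM / YYYY) leniently.

    Anything that is not 4, 6 or 8 digits, or that names an impossible
    calendar date, yields ``precision='invalid'``.  Never raises.
    """
    if raw is None:
        return INVALID_DATE
    s = str(raw).strip()
    if not s.isdigit():
        return INVALID_DATE
    if len(s) == 4:
        return PartialDate(int(s), None, None, "year")
    if len(s) == 6:
        y, m = int(s[:4]), int(s[4:6])
        if 1 <= m <= 12:
            return PartialDate(y, m, None, "month")
        return INVALID_DATE
    if len(s) == 8:
        y, m, d = int(s[:4]), int(s[4:6]), int(s[6:8])
        if _calendar_valid(y, m, d):
            return PartialDate(y, m, d, "day")
        return INVALID_DATE
    return INVALID_DATE


# ---------------------------------------------------------------------------
# Raw table container and reader
# ---------------------------------------------------------------------------


@dataclass
class ReadStats:
    rows_read: dict[str, int] = field(default_factory=dict)
    rows_skipped: dict[str, int] = field(default_factory=dict)


@dataclass
class RawTables:
    """The six FAERS tables of one (or several pooled) quarters.

    All columns are kept as strings exactly as read; typed views are built
    downstream.  Every table carries PRIMARYID and CASEID columns.
    """

    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    ther: pd.DataFrame
    outc: pd.DataFrame
    rpsr: pd.DataFrame
    stats: ReadStats = field(default_factory=ReadStats)

    def table(self, name: str) -> pd.DataFrame:
        return getattr(self, name)

    @staticmethod
    def concat(parts: Iterable["RawTables"]) -> "RawTables":
        parts = list(parts)
        kw = {}
        for name in TABLE_NAMES:
            kw[name] = pd.concat(
                [p.table(name) for p in parts], ignore_index=True
            )
        merged = RawTables(**kw)
        for p in parts:
            for k, v in p.stats.rows_read.items():
                merged.stats.rows_read[k] = merged.stats.rows_read.get(k, 0) + v
            for k, v in p.stats.rows_skipped.items():
                merged.stats.rows_skipped[k] = (
                    merged.stats.rows_skipped.get(k, 0) + v
                )
        return merged


class MissingColumnError(ValueError):
    """A mandatory column (PRIMARYID/CASEID) is absent from a file."""


def _read_dollar_file(path: Path, table: str, stats: ReadStats) -> pd.DataFrame:
    # FAERS files contain occasional non-UTF8 bytes; latin-1 never fails.
    text = Path(path).read_text(encoding="latin-1", errors="replace")
    lines = text.splitlines()
    if not lines:
        raise ValueError(f"{path}: empty file (no header line)")
    header = [h.strip().upper() for h in lines[0].split("$")]
    for required in ("PRIMARYID", "CASEID"):
        if required not in header:
            raise MissingColumnError(
                f"{path}: mandatory column {required} missing from header"
            )
    ncol = len(header)
    rows: list[list[str]] = []
    skipped = 0
    for line in lines[1:]:
        if not line.strip():
            continue
        fields = line.split("$")
        if len(fields) != ncol:
            skipped += 1
            continue
        rows.append(fields)
    if skipped:
        logger.warning("%s: skipped %d malformed rows", path, skipped)
    stats.rows_read[table] = stats.rows_read.get(table, 0) + len(rows)
    stats.rows_skipped[table] = stats.rows_skipped.get(table, 0) + skipped
    df = pd.DataFrame(rows, columns=header, dtype=str)
    logger.info("%s: %d rows (%d skipped)", path, len(rows), skipped)
    return df


def read_quarter(paths: Mapping[str, Path | str]) -> RawTables:
    """Read one quarter's six tables from ``$``-delimited files.

    Parameters
    ----------
    paths
        Mapping from table role (``demo``, ``drug``, ``reac``, ``ther``,
        ``outc``, ``rpsr``) to file path.  Missing optional tables yield
        empty frames; DEMO is mandatory.
    """
    stats = ReadStats()
    frames: dict[str, pd.DataFrame] = {}
    if "demo" not in paths:
        raise ValueError("a DEMO file path is required")
    for name in TABLE_NAMES:
        if name in paths:
            frames[name] = _read_dollar_file(Path(paths[name]), name, stats)
        else:
            frames[name] = pd.DataFrame(columns=["PRIMARYID", "CASEID"], dtype=str)
    return RawTables(stats=stats, **frames)


def find_quarter_files(directory: Path | str) -> dict[str, Path]:
    """Locate FAERS-style ``<TABLE><yy>Q<q>.txt`` files in a directory."""
    directory = Path(directory)
    out: dict[str, Path] = {}
    for name in TABLE_NAMES:
        hits = sorted(directory.glob(f"{name.upper()}*.txt"))
        if hits:
            out[name] = hits[0]
    return out


# ---------------------------------------------------------------------------
# Deduplication
# ---------------------------------------------------------------------------


def _primaryid_key(pid: str) -> tuple[int, int | str]:
    s = str(pid).strip()
    # numeric ids compare numerically; anything else lexicographically after
    return (0, int(s)) if s.isdigit() else (1, s)


@dataclass
class DedupStats:
    n_input: int
    n_survivors: int
    n_unparseable_fda_dt: int

    @property
    def n_removed(self) -> int:
        return self.n_input - self.n_survivors


def deduplicate(demo: pd.DataFrame) -> tuple[pd.DataFrame, DedupStats]:
    """Keep one DEMO row per CASEID: latest FDA_DT, then highest PRIMARYID.

    Partial FDA_DT values are ordered zero-filled by (year, month, day);
    CASEIDs whose every candidate has an unparseable FDA_DT fall back to the
    highest PRIMARYID alone (logged).  Returns the surviving rows (original
    column set, original order within survivors is by CASEID) and counts.
    """
    if demo.empty:
        return demo.copy(), DedupStats(0, 0, 0)
    df = demo.copy()
    parsed = df["FDA_DT"].map(parse_date) if "FDA_DT" in df else None
    if parsed is None:
        df["_dt_key"] = [(0, 0, 0)] * len(df)
        n_bad = len(df)
    else:
        df["_dt_key"] = [p.sort_key for p in parsed]
        bad = [p.precision == "invalid" for p in parsed]
        n_bad = int(sum(bad))
        if n_bad:
            logger.warning(
                "deduplicate: %d rows with unparseable FDA_DT "
                "(ordered by PRIMARYID only)",
                n_bad,
            )
    df["_pid_key"] = df["PRIMARYID"].map(_primaryid_key)
    df = df.sort_values(
        ["CASEID", "_dt_key", "_pid_key"], kind="mergesort"
    )
    survivors = df.groupby("CASEID", sort=False).tail(1)
    survivors = survivors.drop(columns=["_dt_key", "_pid_key"])
    stats = DedupStats(len(demo), len(survivors), n_bad)
    logger.info(
        "deduplicate: %d rows -> %d cases (%d removed)",
        stats.n_input,
        stats.n_survivors,
        stats.n_removed,
    )
    return survivors.reset_index(drop=True), stats


def restrict_to_cases(tables: RawTables, primaryids: Iterable[str]) -> RawTables:
    """Drop rows of every table whose PRIMARYID did not survive dedup."""
    keep = set(str(p) for p in primaryids)
    kw = {
        name: tables.table(name)[
            tables.table(name)["PRIMARYID"].astype(str).isin(keep)
        ].reset_index(drop=True)
        for name in TABLE_NAMES
    }
    return RawTables(stats=tables.stats, **kw)


# ---------------------------------------------------------------------------
# Typed report cases
# ---------------------------------------------------------------------------


@dataclass
class ReportCase:
    """One deduplicated safety report."""

    primaryid: str
    caseid: str
    fda_dt: PartialDate
    event_dt: PartialDate
    age_years: float | None
    sex: str  # 'female' | 'male' | 'unknown'
    weight_kg: float | None
    country: str | None
    reporter_occupation: str | None
    outcomes: frozenset[str] = frozenset()


def _parse_age(age: str | None, unit: str | None) -> float | None:
    try:
        value = float(str(age).strip())
    except (TypeError, ValueError):
        return None
    mult = AGE_UNIT_TO_YEARS.get(str(unit).strip().upper(), 1.0)
    years = value * mult
    return years if 0 <= years <= 150 else None


_SEX_MAP = {"F": "female", "M": "male"}


def build_report_cases(
    demo: pd.DataFrame, outc: pd.DataFrame | None = None
) -> list[ReportCase]:
    """Assemble typed cases from a deduplicated DEMO frame plus outcomes."""
    outcomes_by_pid: dict[str, set[str]] = {}
    if outc is not None and not outc.empty and "OUTC_COD" in outc:
        for pid, code in zip(outc["PRIMARYID"], outc["OUTC_COD"]):
            code = str(code).strip().upper()
            if code in OUTCOME_CODES:
                outcomes_by_pid.setdefault(str(pid), set()).add(code)
    cases = []
    get = lambda row, col: row.get(col) if col in row else None  # noqa: E731
    for _, row in demo.iterrows():
        pid = str(row["PRIMARYID"])
        wt = get(row, "WT")
        try:
            weight = float(str(wt).strip())
            if weight <= 0:
                weight = None
        except (TypeError, ValueError):
            weight = None
        country = str(get(row, "OCCR_COUNTRY") or "").strip() or None
        occp = str(get(row, "OCCP_COD") or "").strip().upper() or None
        cases.append(
            ReportCase(
                primaryid=pid,
                caseid=str(row["CASEID"]),
                fda_dt=parse_date(get(row, "FDA_DT")),
                event_dt=parse_date(get(row, "EVENT_DT")),
                age_years=_parse_age(get(row, "AGE"), get(row, "AGE_COD")),
                sex=_SEX_MAP.get(str(get(row, "SEX") or "").strip().upper(), "unknown"),
                weight_kg=weight,
                country=country,
                reporter_occupation=occp,
                outcomes=frozenset(outcomes_by_pid.get(pid, set())),
            )
        )
    return cases
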