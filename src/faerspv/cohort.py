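"""Cohort construction: event matching, primary-suspect filtering, drug mapping.

Event-positive cases are identified at the MedDRA preferred-term (PT) level
from a user-supplied PT list (code preferred, normalized name as fallback).
Drug mentions are restricted to the primary-suspect (PS) role and verbatim
drug names are collapsed to canonical ingredients with ATC codes through a
many-to-one synonym dictionary.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .ingest import RawTables, ReportCase, build_report_cases

logger = logging.getLogger(__name__)

ROLE_CODES = ("PS", "SS", "C", "I")

#: dosage/form tokens stripped from the tail of verbatim drug names
DEFAULT_STRIP_SUFFIXES = (
    "TABLET", "TABLETS", "TAB", "CAPSULE", "CAPSULES", "CAP", "INJECTION",
    "INJ", "SOLUTION", "ORAL", "CREAM", "GEL", "PATCH", "SPRAY", "SYRUP",
    "SUSPENSION", "ER", "XR", "SR", "HCL",
)

_DOSE_RE = re.compile(r"^\d+(\.\d+)?(MG|MCG|G|ML|IU|%)(/\S+)?$")


def normalize_name(raw: str) -> str:
    """Case-fold, trim and collapse internal whitespace."""
    return " ".join(str(raw).split()).casefold()


def strip_form_tokens(
    name: str, suffixes: tuple[str, ...] = DEFAULT_STRIP_SUFFIXES
) -> str:
    """Drop trailing dosage/pharmaceutical-form tokens from a name."""
    tokens = name.split()
    suffix_set = {s.casefold() for s in suffixes}
    while len(tokens) > 1:
        tail = tokens[-1]
        if tail in suffix_set or _DOSE_RE.match(tail.upper()):
            tokens.pop()
        else:
            break
    return " ".join(tokens)


# ---------------------------------------------------------------------------
# PT list
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PTList:
    """The event definition: a set of MedDRA preferred terms.

    Matching is by PT code when the reaction row carries one, otherwise by
    normalized (case-folded, whitespace-collapsed) PT name.
    """

    codes: frozenset[int]
    names: frozenset[str]

    def __post_init__(self):
        if not self.codes and not self.names:
            raise ValueError("PT list must not be empty")

    @classmethod
    def from_pairs(cls, pairs) -> "PTList":
        codes, names = set(), set()
        for code, name in pairs:
            if code not in (None, ""):
                codes.add(int(code))
            if name:
                names.add(normalize_name(name))
        return cls(frozenset(codes), frozenset(names))

    @classmethod
    def from_csv(cls, path: Path | str) -> "PTList":
        """Load a two-column (pt_code, pt_name) CSV; either may be blank."""
        pairs = []
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                pairs.append((row.get("pt_code") or None, row.get("pt_name")))
        return cls.from_pairs(pairs)

    def matches(self, pt_name: str | None, pt_code=None) -> bool:
        if pt_code not in (None, ""):
            try:
                return int(pt_code) in self.codes
            except (TypeError, ValueError):
                pass
        if pt_name is None:
            return False
        return normalize_name(pt_name) in self.names


def default_pt_list() -> PTList:
    """The bundled stand-in venous-thromboembolism PT list.

    A placeholder set of common VTE preferred terms shipped for testing and
    demonstration; real analyses should supply their own MedDRA-derived list.
    """
    path = Path(__file__).parent / "data" / "vte_pt_standin.csv"
    return PTList.from_csv(path)


# ---------------------------------------------------------------------------
# Drug dictionary
# ---------------------------------------------------------------------------


@dataclass
class DrugDictionary:
    """Many-to-one map: normalized verbatim drug name -> ingredient + ATC.

    ``mapping[name] = (ingredient, atc_codes)`` where ``atc_codes`` is a
    (possibly empty) tuple of 7-character ATC codes.  Ingredients with no
    ATC code are carried with an empty tuple and reported as unmapped-to-ATC.
    """

    mapping: dict[str, tuple[str, tuple[str, ...]]] = field(default_factory=dict)
    strip_suffixes: tuple[str, ...] = DEFAULT_STRIP_SUFFIXES

    @classmethod
    def from_csv(cls, path: Path | str) -> "DrugDictionary":
        """Load columns verbatim, ingredient, atc_code (';'-separated)."""
        mapping: dict[str, tuple[str, tuple[str, ...]]] = {}
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                key = normalize_name(row["verbatim"])
                atc = tuple(
                    c.strip().upper()
                    for c in (row.get("atc_code") or "").split(";")
                    if c.strip()
                )
                ingredient = normalize_name(row["ingredient"])
                if key in mapping and mapping[key][0] != ingredient:
                    logger.warning("drug dictionary: conflicting entry for %r", key)
                mapping[key] = (ingredient, atc)
        return cls(mapping)

    def lookup(self, verbatim: str) -> tuple[str, tuple[str, ...]] | None:
        """Resolve a verbatim name; None when unmapped."""
        key = normalize_name(verbatim)
        hit = self.mapping.get(key)
        if hit is None:
            hit = self.mapping.get(strip_form_tokens(key, self.strip_suffixes))
        return hit


def atc_level1(atc_codes: tuple[str, ...]) -> str | None:
    """Anatomical main group: the first letter of the first ATC code."""
    return atc_codes[0][0] if atc_codes else None


def atc_level3(atc_codes: tuple[str, ...]) -> str | None:
    """Pharmacological subgroup: the first four characters."""
    return atc_codes[0][:4] if atc_codes else None


# ---------------------------------------------------------------------------
# Event matching and PS filtering
# ---------------------------------------------------------------------------


def match_event(reac: pd.DataFrame, pt_list: PTList) -> set[str]:
    """PRIMARYIDs of cases with at least one reaction PT on the list.

    A case counts once no matter how many of its PTs match.
    """
    if not isinstance(pt_list, PTList):
        raise TypeError("pt_list must be a PTList")
    if reac.empty:
        return set()
    codes = reac["PT_CODE"] if "PT_CODE" in reac.columns else [None] * len(reac)
    positives = {
        str(pid)
        for pid, name, code in zip(reac["PRIMARYID"], reac.get("PT", [None] * len(reac)), codes)
        if pt_list.matches(name, code)
    }
    logger.info("match_event: %d event-positive cases", len(positives))
    return positives


def filter_primary_suspect(
    drug: pd.DataFrame, dictionary: DrugDictionary | None = None
) -> pd.DataFrame:
    """PS-role drug mentions, one row per (case, ingredient) pair.

    Returns a frame with columns PRIMARYID, VERBATIM, INGREDIENT, ATC,
    ATC1, ATC3, MAPPED.  Unmapped names keep their normalized verbatim
    string as the ingredient and are flagged MAPPED=False.
    """
    if drug.empty:
        return pd.DataFrame(
            columns=["PRIMARYID", "VERBATIM", "INGREDIENT", "ATC", "ATC1", "ATC3", "MAPPED"]
        )
    ps = drug[drug["ROLE_COD"].astype(str).str.strip().str.upper() == "PS"]
    rows = []
    for pid, verbatim in zip(ps["PRIMARYID"], ps["DRUGNAME"]):
        hit = dictionary.lookup(verbatim) if dictionary is not None else None
        if hit is not None:
            ingredient, atc = hit
            mapped = True
        else:
            ingredient, atc, mapped = normalize_name(verbatim), (), False
        rows.append(
            {
                "PRIMARYID": str(pid),
                "VERBATIM": str(verbatim),
                "INGREDIENT": ingredient,
                "ATC": ";".join(atc),
                "ATC1": atc_level1(atc),
                "ATC3": atc_level3(atc),
                "MAPPED": mapped,
            }
        )
    out = pd.DataFrame(rows)
    # one (case, ingredient) pair counts once, however many PS rows repeat it
    out = out.drop_duplicates(subset=["PRIMARYID", "INGREDIENT"]).reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# Analysis dataset
# ---------------------------------------------------------------------------


@dataclass
class AnalysisDataset:
    """Everything downstream stages need, at the deduplicated-case level."""

    cases: list[ReportCase]
    mentions: pd.DataFrame  # PS mentions, one row per (case, ingredient)
    event_positive: set[str]
    n_total_reports: int
    ther: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self):
        pids = {c.primaryid for c in self.cases}
        if not self.event_positive <= pids:
            raise ValueError("event_positive contains unknown PRIMARYIDs")
        if self.n_total_reports < len(self.event_positive):
            raise ValueError("total reports below event-positive count")

    @property
    def case_index(self) -> dict[str, ReportCase]:
        return {c.primaryid: c for c in self.cases}

    def drug_universe(self, mapped_only: bool = True) -> list[str]:
        m = self.mentions
        if mapped_only and "MAPPED" in m.columns:
            m = m[m["MAPPED"]]
        return sorted(m["INGREDIENT"].unique())


def build_dataset(
    tables: RawTables,
    pt_list: PTList,
    dictionary: DrugDictionary | None = None,
) -> AnalysisDataset:
    """Assemble the analysis dataset from deduplicated raw tables."""
    cases = build_report_cases(tables.demo, tables.outc)
    mentions = filter_primary_suspect(tables.drug, dictionary)
    positives = match_event(tables.reac, pt_list)
    positives &= {c.primaryid for c in cases}
    return AnalysisDataset(
        cases=cases,
        mentions=mentions,
        event_positive=positives,
        n_total_reports=len(cases),
        ther=tables.ther,
    )
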