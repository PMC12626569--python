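"""Demographic/outcome summary tables and the annual reporting trend."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

AGE_BINS = ((0, 18), (18, 45), (45, 65), (65, 75), (75, np.inf))
AGE_LABELS = ("<18", "18-44", "45-64", "65-74", ">=75")

#: tally one outcome per case, most severe first
OUTCOME_PRIORITY = ("DE", "LT", "DS", "HO", "CA", "RI", "OT")
OUTCOME_NAMES = {
    "DE": "Death",
    "LT": "Life-threatening",
    "DS": "Disability",
    "HO": "Hospitalization - initial or prolonged",
    "CA": "Congenital anomaly",
    "RI": "Required intervention to prevent",
    "OT": "Other serious (important medical event)",
}

OCCUPATION_NAMES = {
    "MD": "Physician",
    "PH": "Pharmacist",
    "CN": "Consumer",
    "LW": "Lawyer",
    "HP": "Other health-professional",
    "OT": "Other",
}


def _percent(count: int, denom: int) -> float:
    return round(100.0 * count / denom, 1) if denom else float("nan")


def prioritized_outcome(outcomes) -> str | None:
    """The single most severe outcome code of a case, or None."""
    for code in OUTCOME_PRIORITY:
        if code in outcomes:
            return code
    return None


def summarize(dataset) -> pd.DataFrame:
    """Tidy demographic/outcome summary of the event cohort.

    One row per (variable, level) with columns variable, level, available_n,
    count, percent (categorical) or value columns (continuous median/IQR).
    Percentages for age groups, countries, outcomes and occupations use the
    variable's available n; sex uses the full cohort (unknown is a level).
    """
    cases = dataset.cases
    n_total = len(cases)
    if n_total == 0:
        raise ValueError("empty dataset")
    rows: list[dict] = []

    ages = np.array([c.age_years for c in cases if c.age_years is not None])
    if len(ages):
        q1, med, q3 = np.quantile(ages, [0.25, 0.5, 0.75])
        rows.append(
            {
                "variable": "age_years", "level": "median (IQR)",
                "available_n": len(ages), "count": None, "percent": None,
                "median": float(med), "q1": float(q1), "q3": float(q3),
            }
        )
        for (lo, hi), label in zip(AGE_BINS, AGE_LABELS):
            count = int(np.sum((ages >= lo) & (ages < hi)))
            rows.append(
                {
                    "variable": "age_group", "level": label,
                    "available_n": len(ages), "count": count,
                    "percent": _percent(count, len(ages)),
                }
            )

    weights = np.array([c.weight_kg for c in cases if c.weight_kg is not None])
    if len(weights):
        q1, med, q3 = np.quantile(weights, [0.25, 0.5, 0.75])
        rows.append(
            {
                "variable": "weight_kg", "level": "median (IQR)",
                "available_n": len(weights), "count": None, "percent": None,
                "median": float(med), "q1": float(q1), "q3": float(q3),
            }
        )

    for level in ("female", "male", "unknown"):
        count = sum(1 for c in cases if c.sex == level)
        rows.append(
            {
                "variable": "sex", "level": level, "available_n": n_total,
                "count": count, "percent": _percent(count, n_total),
            }
        )

    countries = pd.Series([c.country for c in cases if c.country]).value_counts()
    n_country = int(countries.sum())
    for level, count in countries.items():
        rows.append(
            {
                "variable": "country", "level": level, "available_n": n_country,
                "count": int(count), "percent": _percent(int(count), n_country),
            }
        )

    outcome_codes = [prioritized_outcome(c.outcomes) for c in cases]
    outcome_codes = [o for o in outcome_codes if o is not None]
    n_outcome = len(outcome_codes)
    tally = pd.Series(outcome_codes).value_counts()
    for code in OUTCOME_PRIORITY:
        if code in tally:
            rows.append(
                {
                    "variable": "outcome", "level": OUTCOME_NAMES[code],
                    "available_n": n_outcome, "count": int(tally[code]),
                    "percent": _percent(int(tally[code]), n_outcome),
                }
            )

    occs = [c.reporter_occupation for c in cases if c.reporter_occupation]
    n_occ = len(occs)
    occ_tally = pd.Series(
        [OCCUPATION_NAMES.get(o, "Other") for o in occs]
    ).value_counts()
    for level, count in occ_tally.items():
        rows.append(
            {
                "variable": "reporter_occupation", "level": level,
                "available_n": n_occ, "count": int(count),
                "percent": _percent(int(count), n_occ),
            }
        )

    return pd.DataFrame(rows)


def annual_series(dataset) -> pd.DataFrame:
    """Reports and death reports per receipt year (FDA_DT).

    Cases with only year precision still contribute; invalid FDA_DT rows
    are excluded and logged.  Death = DE among the case's outcome codes.
    """
    rows = []
    n_excluded = 0
    for case in dataset.cases:
        year = case.fda_dt.year
        if case.fda_dt.precision == "invalid" or year is None:
            n_excluded += 1
            continue
        rows.append((year, "DE" in case.outcomes))
    if n_excluded:
        logger.warning("annual_series: %d cases without usable FDA_DT", n_excluded)
    if not rows:
        return pd.DataFrame(columns=["year", "total_reports", "death_reports"])
    df = pd.DataFrame(rows, columns=["year", "death"])
    out = (
        df.groupby("year")
        .agg(total_reports=("death", "size"), death_reports=("death", "sum"))
        .reset_index()
        .sort_values("year")
        .reset_index(drop=True)
    )
    out["death_reports"] = out["death_reports"].astype(int)
    return out
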