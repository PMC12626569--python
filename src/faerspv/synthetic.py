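"""Seeded generator of FAERS-like quarterly tables with known ground truth.

The generator emulates the statistical structure of a spontaneous-report
database at desk scale: multi-table case records keyed by PRIMARYID/CASEID,
follow-up duplicates sharing a CASEID, role-coded drug mentions with synonym
spellings, PT-coded reactions, partial or missing dates, configurable
drug-event association strength on the reporting-ratio scale, and
Weibull-distributed onset times.  Every draw is deterministic given the
seed, and the exact 2x2 counts, duplicate map and per-record onset times
are returned alongside the tables so each pipeline stage can be checked
against the truth.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import DrugDictionary, PTList, normalize_name
from .ingest import RawTables, TABLE_NAMES

# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class DrugSpec:
    """One simulated ingredient with its reporting behaviour."""

    ingredient: str
    synonyms: list[str] = field(default_factory=list)
    atc_code: str = ""
    background_use_prob: float = 0.01
    true_rr: float = 1.0          # reporting-rate multiplier for the target event
    tto_alpha: float = 120.0      # Weibull scale of onset times, days
    tto_beta: float = 0.649       # Weibull shape

    def all_names(self) -> list[str]:
        return [self.ingredient] + list(self.synonyms)


DEFAULT_TARGET_PTS: tuple[tuple[int, str], ...] = (
    (10051055, "Deep vein thrombosis"),
    (10037377, "Pulmonary embolism"),
    (10047249, "Venous thrombosis"),
)

DEFAULT_BACKGROUND_PTS: tuple[tuple[int, str], ...] = (
    (10028813, "Nausea"),
    (10019211, "Headache"),
    (10016558, "Fatigue"),
    (10012735, "Diarrhoea"),
    (10013968, "Dyspnoea"),
    (10037844, "Rash"),
    (10047700, "Vomiting"),
    (10012174, "Dizziness"),
)

#: demographic mixes for the simulated cohort (sex / country / outcome /
#: reporter-occupation marginals of a large VTE safety cohort)
DEFAULT_SEX_PROBS = {"F": 0.55, "M": 0.35, "": 0.10}
DEFAULT_COUNTRY_PROBS = {
    "US": 0.57, "FR": 0.061, "DE": 0.053, "CA": 0.052, "GB": 0.051, "OT": 0.213,
}
DEFAULT_OUTCOME_PROBS = {
    "HO": 0.44, "OT": 0.315, "DE": 0.138, "LT": 0.082,
    "DS": 0.008, "RI": 0.002, "CA": 0.0005, "": 0.0145,
}
DEFAULT_OCCP_PROBS = {"MD": 0.33, "CN": 0.25, "HP": 0.17, "PH": 0.064,
                      "LW": 0.061, "": 0.125}


def example_drugs() -> list[DrugSpec]:
    """A small plausible drug panel: two associated drugs, three nulls."""
    return [
        DrugSpec("dienogest", ["visanne", "dienogest 2mg tablet"],
                 "G03DB08", 0.01, true_rr=8.0, tto_alpha=300, tto_beta=0.8),
        DrugSpec("rivaroxaban", ["xarelto", "rivaroxaban 10mg tablet"],
                 "B01AF01", 0.015, true_rr=4.0, tto_alpha=60, tto_beta=0.7),
        DrugSpec("metformin", ["glucophage", "metformin hcl"],
                 "A10BA02", 0.03, true_rr=1.0),
        DrugSpec("amoxicillin", ["amoxil", "amoxicillin capsule"],
                 "J01CA04", 0.02, true_rr=1.0),
        DrugSpec("ibuprofen", ["advil", "ibuprofen 200mg"],
                 "M01AE01", 0.04, true_rr=1.0),
    ]


@dataclass
class SyntheticConfig:
    """Everything the generator needs; fully determines the output with seed."""

    n_cases: int = 10_000
    duplicate_fraction: float = 0.05
    base_event_prob: float = 0.01
    drugs: list[DrugSpec] = field(default_factory=example_drugs)
    target_pts: tuple[tuple[int, str], ...] = DEFAULT_TARGET_PTS
    background_pts: tuple[tuple[int, str], ...] = DEFAULT_BACKGROUND_PTS
    sex_probs: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SEX_PROBS))
    country_probs: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_COUNTRY_PROBS))
    outcome_probs: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_OUTCOME_PROBS))
    occp_probs: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_OCCP_PROBS))
    age_mean: float = 56.0
    age_sd: float = 22.0
    age_missing_prob: float = 0.3
    weight_log_median: float = 80.0
    weight_log_sd: float = 0.34
    weight_missing_prob: float = 0.8
    event_dt_day_prob: float = 0.6    # remaining mass: month precision / missing
    event_dt_month_prob: float = 0.1
    first_year: int = 2004
    last_year: int = 2023
    seed: int = 0

    def validate(self) -> None:
        if self.n_cases <= 0:
            raise ValueError("n_cases must be positive")
        if not 0 <= self.duplicate_fraction < 1:
            raise ValueError("duplicate_fraction must be in [0,1)")
        for d in self.drugs:
            if not 0 < d.background_use_prob <= 1:
                raise ValueError(f"{d.ingredient}: bad background_use_prob")
            if d.true_rr <= 0 or d.tto_alpha <= 0 or d.tto_beta <= 0:
                raise ValueError(f"{d.ingredient}: rr/alpha/beta must be positive")
            scaled = self.base_event_prob * d.true_rr
            if scaled > 1:
                raise ValueError(
                    f"{d.ingredient}: scaled event probability {scaled:.3f} > 1"
                )
        for name, probs in (
            ("sex", self.sex_probs), ("country", self.country_probs),
            ("outcome", self.outcome_probs), ("occupation", self.occp_probs),
        ):
            if abs(sum(probs.values()) - 1.0) > 1e-6:
                raise ValueError(f"{name} probabilities must sum to 1")

    def pt_list(self) -> PTList:
        return PTList.from_pairs(self.target_pts)

    def drug_dictionary(self) -> DrugDictionary:
        mapping = {}
        for d in self.drugs:
            atc = (d.atc_code,) if d.atc_code else ()
            for name in d.all_names():
                mapping[normalize_name(name)] = (normalize_name(d.ingredient), atc)
        return DrugDictionary(mapping)

    @classmethod
    def from_yaml(cls, path: Path | str) -> "SyntheticConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw["drugs"] = [DrugSpec(**d) for d in raw.get("drugs", [])] or example_drugs()
        if "target_pts" in raw:
            raw["target_pts"] = tuple((int(c), n) for c, n in raw["target_pts"])
        if "background_pts" in raw:
            raw["background_pts"] = tuple((int(c), n) for c, n in raw["background_pts"])
        return cls(**raw)

    def to_yaml(self, path: Path | str) -> None:
        data = dataclasses.asdict(self)
        data["target_pts"] = [list(p) for p in self.target_pts]
        data["background_pts"] = [list(p) for p in self.background_pts]
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------


@dataclass
class GroundTruth:
    """Exact per-case generator state for oracle checks."""

    caseids: np.ndarray           # str
    primaryids: np.ndarray        # str, the original (version-1) ids
    ps_ingredient: np.ndarray     # str, canonical ingredient per case
    event: np.ndarray             # bool
    tto_days: np.ndarray          # float, nan when no onset emitted at day precision
    duplicate_map: dict[str, str]  # duplicate PRIMARYID -> original PRIMARYID

    @property
    def n_cases(self) -> int:
        return len(self.caseids)

    def pair_counts(self) -> dict[str, tuple[int, int, int, int]]:
        """Brute-force 2x2 recount per ingredient against the target event."""
        out = {}
        n = self.n_cases
        n_event = int(self.event.sum())
        for drug in np.unique(self.ps_ingredient):
            on = self.ps_ingredient == drug
            a = int((on & self.event).sum())
            b = int(on.sum()) - a
            c = n_event - a
            out[str(drug)] = (a, b, c, n - a - b - c)
        return out

    def to_json(self, path: Path | str) -> None:
        payload = {
            "n_cases": self.n_cases,
            "pair_counts": {k: list(v) for k, v in self.pair_counts().items()},
            "duplicate_map": self.duplicate_map,
            "caseids": self.caseids.tolist(),
            "ps_ingredient": self.ps_ingredient.tolist(),
            "event": self.event.astype(int).tolist(),
            "tto_days": [None if np.isnan(t) else t for t in self.tto_days],
        }
        Path(path).write_text(json.dumps(payload))


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


def _choice(rng, options: dict[str, float], n: int) -> np.ndarray:
    keys = np.array(list(options.keys()), dtype=object)
    probs = np.array(list(options.values()), dtype=float)
    probs = probs / probs.sum()
    return keys[rng.choice(len(keys), size=n, p=probs)]


def _fmt_dates(days: np.ndarray) -> np.ndarray:
    """int days-since-epoch -> YYYYMMDD strings."""
    ts = pd.to_datetime(days, unit="D", origin="unix")
    return ts.strftime("%Y%m%d").to_numpy(dtype=object)


def generate(config: SyntheticConfig) -> tuple[RawTables, GroundTruth]:
    """Draw a full synthetic quarter (pooled) and its ground truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_cases
    drugs = config.drugs
    n_drugs = len(drugs)

    caseid_num = 10_000_000 + np.arange(n)
    caseids = caseid_num.astype(str).astype(object)
    primaryid_num = caseid_num * 10 + 1
    primaryids = primaryid_num.astype(str).astype(object)

    # --- exposure and primary-suspect assignment -------------------------
    use_probs = np.array([d.background_use_prob for d in drugs])
    exposure = rng.random((n_drugs, n)) < use_probs[:, None]
    none_exposed = ~exposure.any(axis=0)
    if none_exposed.any():
        forced = rng.choice(n_drugs, size=int(none_exposed.sum()),
                            p=use_probs / use_probs.sum())
        exposure[forced, np.flatnonzero(none_exposed)] = True
    counts = exposure.sum(axis=0).astype(np.int32)
    position = (rng.random(n) * counts).astype(np.int32) + 1  # 1..count
    cum = np.cumsum(exposure, axis=0, dtype=np.int32)
    ps_idx = np.argmax((cum == position[None, :]) & exposure, axis=0)

    # --- target event, scaled by the PS drug's reporting ratio -----------
    rr = np.array([d.true_rr for d in drugs])
    p_event = config.base_event_prob * rr[ps_idx]
    event = rng.random(n) < p_event

    # --- dates ------------------------------------------------------------
    day0 = (pd.Timestamp(config.first_year, 1, 1) - pd.Timestamp(1970, 1, 1)).days
    day1 = (pd.Timestamp(config.last_year, 12, 31) - pd.Timestamp(1970, 1, 1)).days
    start_days = rng.integers(day0, day1 + 1, size=n)
    alphas = np.array([d.tto_alpha for d in drugs])[ps_idx]
    betas = np.array([d.tto_beta for d in drugs])[ps_idx]
    onset = alphas * rng.weibull(betas, size=n)
    event_days = start_days + np.floor(onset).astype(np.int64)
    fda_days = np.where(event, event_days, start_days) + rng.integers(30, 400, size=n)

    start_str = _fmt_dates(start_days)
    event_full = _fmt_dates(event_days)
    u = rng.random(n)
    day_p, month_p = config.event_dt_day_prob, config.event_dt_month_prob
    event_str = np.where(
        u < day_p, event_full,
        np.where(u < day_p + month_p,
                 np.array([s[:6] for s in event_full], dtype=object), ""),
    ).astype(object)
    event_str[~event] = ""  # only event cases carry an onset date
    fda_str = _fmt_dates(fda_days)

    # recoverable onset time: day-precision event date and an event present
    tto = np.where(event & (u < day_p),
                   np.floor(onset) + 0.5, np.nan)

    # --- demographics ------------------------------------------------------
    sex = _choice(rng, config.sex_probs, n)
    age = np.round(np.clip(rng.normal(config.age_mean, config.age_sd, n), 0, 105), 0)
    age_str = np.where(rng.random(n) < config.age_missing_prob, "",
                       age.astype(int).astype(str)).astype(object)
    weight = np.round(config.weight_log_median
                      * np.exp(rng.normal(0, config.weight_log_sd, n)), 1)
    weight_str = np.where(rng.random(n) < config.weight_missing_prob, "",
                          weight.astype(str)).astype(object)
    country = _choice(rng, config.country_probs, n)
    occp = _choice(rng, config.occp_probs, n)
    outcome = _choice(rng, config.outcome_probs, n)

    demo = pd.DataFrame(
        {
            "PRIMARYID": primaryids, "CASEID": caseids,
            "FDA_DT": fda_str, "EVENT_DT": event_str,
            "AGE": age_str, "AGE_COD": np.where(age_str == "", "", "YR"),
            "SEX": sex, "WT": weight_str,
            "WT_COD": np.where(weight_str == "", "", "KG"),
            "OCCR_COUNTRY": country, "OCCP_COD": occp,
        },
        dtype=object,
    )

    # --- drug rows: one PS mention plus concomitant mentions --------------
    name_pool = [np.array(d.all_names(), dtype=object) for d in drugs]
    ps_names = np.empty(n, dtype=object)
    for k in range(n_drugs):
        mask = ps_idx == k
        m = int(mask.sum())
        if m:
            ps_names[mask] = name_pool[k][rng.integers(0, len(name_pool[k]), m)]
    drug_rows = {
        "PRIMARYID": list(primaryids), "CASEID": list(caseids),
        "DRUG_SEQ": ["1"] * n, "ROLE_COD": ["PS"] * n,
        "DRUGNAME": list(ps_names),
    }
    seq = np.full(n, 2)
    for k in range(n_drugs):
        conc = np.flatnonzero(exposure[k] & (ps_idx != k))
        if len(conc) == 0:
            continue
        names = name_pool[k][rng.integers(0, len(name_pool[k]), len(conc))]
        drug_rows["PRIMARYID"] += [primaryids[i] for i in conc]
        drug_rows["CASEID"] += [caseids[i] for i in conc]
        drug_rows["DRUG_SEQ"] += [str(seq[i]) for i in conc]
        drug_rows["ROLE_COD"] += ["C"] * len(conc)
        drug_rows["DRUGNAME"] += list(names)
        seq[conc] += 1
    drug = pd.DataFrame(drug_rows, dtype=object)

    # --- reactions: target PT for event cases, background PTs for all -----
    target = np.array(config.target_pts, dtype=object)
    bg = np.array(config.background_pts, dtype=object)
    reac_pid, reac_case, reac_pt, reac_code = [], [], [], []
    ev_idx = np.flatnonzero(event)
    t_pick = rng.integers(0, len(target), len(ev_idx))
    for i, k in zip(ev_idx, t_pick):
        reac_pid.append(primaryids[i])
        reac_case.append(caseids[i])
        reac_code.append(str(target[k][0]))
        reac_pt.append(target[k][1])
    # one or two distinct background PTs per case (second drawn by offset)
    k1 = rng.integers(0, len(bg), n)
    k2 = (k1 + 1 + rng.integers(0, len(bg) - 1, n)) % len(bg)
    two = rng.random(n) < 0.5
    for i in range(n):
        reac_pid.append(primaryids[i])
        reac_case.append(caseids[i])
        reac_code.append(str(bg[k1[i]][0]))
        reac_pt.append(bg[k1[i]][1])
        if two[i]:
            reac_pid.append(primaryids[i])
            reac_case.append(caseids[i])
            reac_code.append(str(bg[k2[i]][0]))
            reac_pt.append(bg[k2[i]][1])
    reac = pd.DataFrame(
        {"PRIMARYID": reac_pid, "CASEID": reac_case,
         "PT": reac_pt, "PT_CODE": reac_code},
        dtype=object,
    )

    ther = pd.DataFrame(
        {"PRIMARYID": primaryids, "CASEID": caseids,
         "DSG_DRUG_SEQ": np.full(n, "1", dtype=object), "START_DT": start_str},
        dtype=object,
    )
    has_outc = outcome != ""
    outc = pd.DataFrame(
        {"PRIMARYID": primaryids[has_outc], "CASEID": caseids[has_outc],
         "OUTC_COD": outcome[has_outc]},
        dtype=object,
    )
    rpsr = pd.DataFrame(
        {"PRIMARYID": primaryids, "CASEID": caseids,
         "RPSR_COD": _choice(rng, {"FGN": 0.2, "HP": 0.5, "CSM": 0.3}, n)},
        dtype=object,
    )

    # --- duplicates: clone cases under a later FDA_DT, higher PRIMARYID ---
    n_dup = int(round(config.duplicate_fraction * n))
    duplicate_map: dict[str, str] = {}
    if n_dup:
        dup_idx = rng.choice(n, size=n_dup, replace=False)
        dup_pid = (caseid_num[dup_idx] * 10 + 2).astype(str).astype(object)
        dup_fda = _fmt_dates(fda_days[dup_idx] + rng.integers(10, 200, n_dup))
        dup_demo = demo.iloc[dup_idx].copy()
        dup_demo["PRIMARYID"] = dup_pid
        dup_demo["FDA_DT"] = dup_fda
        demo = pd.concat([demo, dup_demo], ignore_index=True)
        old_to_new = dict(zip((p for p in primaryids[dup_idx]), dup_pid))
        duplicate_map = {new: old for old, new in old_to_new.items()}
        for name, frame in (("drug", drug), ("reac", reac),
                            ("ther", ther), ("outc", outc), ("rpsr", rpsr)):
            sub = frame[frame["PRIMARYID"].isin(old_to_new)].copy()
            sub["PRIMARYID"] = sub["PRIMARYID"].map(old_to_new)
            if name == "drug":
                drug = pd.concat([drug, sub], ignore_index=True)
            elif name == "reac":
                reac = pd.concat([reac, sub], ignore_index=True)
            elif name == "ther":
                ther = pd.concat([ther, sub], ignore_index=True)
            elif name == "outc":
                outc = pd.concat([outc, sub], ignore_index=True)
            else:
                rpsr = pd.concat([rpsr, sub], ignore_index=True)

    tables = RawTables(demo=demo, drug=drug, reac=reac, ther=ther,
                       outc=outc, rpsr=rpsr)
    truth = GroundTruth(
        caseids=np.asarray(caseids, dtype=object),
        primaryids=np.asarray(primaryids, dtype=object),
        ps_ingredient=np.array(
            [normalize_name(drugs[k].ingredient) for k in ps_idx], dtype=object
        ),
        event=event,
        tto_days=tto,
        duplicate_map=duplicate_map,
    )
    return tables, truth


# ---------------------------------------------------------------------------
# Writing quarters to disk
# ---------------------------------------------------------------------------


def write_quarter(
    tables: RawTables, directory: Path | str, quarter: str = "24Q3"
) -> dict[str, Path]:
    """Emit the six tables as ``$``-delimited FAERS-style text files."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name in TABLE_NAMES:
        df = tables.table(name)
        path = directory / f"{name.upper()}{quarter}.txt"
        lines = ["$".join(df.columns)]
        for row in df.itertuples(index=False):
            lines.append("$".join("" if v is None else str(v) for v in row))
        path.write_text("\n".join(lines) + "\n", encoding="latin-1")
        paths[name] = path
    return paths
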