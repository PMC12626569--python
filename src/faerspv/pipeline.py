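"""End-to-end orchestration: ingest -> dedup -> cohort -> signals -> TTO -> descriptives.

A single :class:`RunConfig` (usually loaded from YAML) drives the whole
analysis; every stage writes its table into the output directory and a
manifest records the seed, configuration hash and stage-by-stage report
counts so a run can be audited and reproduced.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .cohort import (AnalysisDataset, DrugDictionary, PTList, build_dataset,
                     default_pt_list)
from .descriptives import annual_series, summarize
from .ingest import (RawTables, deduplicate, find_quarter_files, read_quarter,
                     restrict_to_cases)
from .signals import PriorConfig, SignalThresholds, compute_signals
from .synthetic import SyntheticConfig, generate, write_quarter
from .tto import cumulative_incidence, logrank_test, onset_records, tto_summary_table

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """One reproducible analysis run."""

    input_dirs: list[str] = field(default_factory=list)
    synthetic: SyntheticConfig | None = None
    pt_list_path: str | None = None       # None -> bundled stand-in list
    drug_dict_path: str | None = None
    out_dir: str = "faerspv_out"
    seed: int = 0
    bcpnn_variant: str = "simplified"
    mgps_variant: str = "closed_form"
    yates: bool = True
    thresholds: SignalThresholds = field(default_factory=SignalThresholds)
    prior: PriorConfig = field(default_factory=PriorConfig)
    min_tto_n: int = 10

    @classmethod
    def from_yaml(cls, path: Path | str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "synthetic" in raw and raw["synthetic"] is not None:
            syn = raw["synthetic"]
            if isinstance(syn, dict):
                from .synthetic import DrugSpec
                syn = dict(syn)
                if "drugs" in syn:
                    syn["drugs"] = [DrugSpec(**d) for d in syn["drugs"]]
                raw["synthetic"] = SyntheticConfig(**syn)
        if "thresholds" in raw and isinstance(raw["thresholds"], dict):
            raw["thresholds"] = SignalThresholds(**raw["thresholds"])
        if "prior" in raw and isinstance(raw["prior"], dict):
            raw["prior"] = PriorConfig(**raw["prior"])
        cfg = cls(**raw)
        for p in (cfg.pt_list_path, cfg.drug_dict_path, *cfg.input_dirs):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)
        return cfg


def _config_hash(config: RunConfig) -> str:
    text = repr(config).encode()
    return hashlib.sha256(text).hexdigest()[:16]


def load_tables(config: RunConfig) -> RawTables:
    """Read all configured quarters (or generate the synthetic one)."""
    if config.synthetic is not None:
        syn = config.synthetic
        syn.seed = config.seed
        tables, _ = generate(syn)
        return tables
    if not config.input_dirs:
        raise ValueError("config needs input_dirs or a synthetic section")
    parts = []
    for directory in config.input_dirs:
        paths = find_quarter_files(directory)
        parts.append(read_quarter(paths))
    return RawTables.concat(parts) if len(parts) > 1 else parts[0]


def prepare_dataset(config: RunConfig, tables: RawTables) -> tuple[AnalysisDataset, dict]:
    """Deduplicate and build the analysis dataset; returns stage counts."""
    survivors, dstats = deduplicate(tables.demo)
    tables = restrict_to_cases(tables, survivors["PRIMARYID"])
    tables.demo = survivors
    if config.synthetic is not None:
        pt_list = config.synthetic.pt_list()
        dictionary = config.synthetic.drug_dictionary()
    else:
        pt_list = (PTList.from_csv(config.pt_list_path)
                   if config.pt_list_path else default_pt_list())
        dictionary = (DrugDictionary.from_csv(config.drug_dict_path)
                      if config.drug_dict_path else None)
    dataset = build_dataset(tables, pt_list, dictionary)
    counts = {
        "demo_rows_in": dstats.n_input,
        "cases_after_dedup": dstats.n_survivors,
        "dedup_removed": dstats.n_removed,
        "event_positive_cases": len(dataset.event_positive),
        "ps_mentions": int(len(dataset.mentions)),
        "distinct_drugs": len(dataset.drug_universe(mapped_only=False)),
    }
    return dataset, counts


def run(config: RunConfig) -> Path:
    """Execute the full pipeline; returns the artifact directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "ingest"
    try:
        tables = load_tables(config)
        stage = "dedup/cohort"
        dataset, counts = prepare_dataset(config, tables)
        stage = "signals"
        signal_table = compute_signals(
            dataset,
            prior=config.prior,
            thresholds=config.thresholds,
            bcpnn_variant=config.bcpnn_variant,
            mgps_variant=config.mgps_variant,
            yates=config.yates,
        )
        signal_table.to_csv(out / "signals.csv", index=False)
        positives = signal_table[signal_table["combined"]]
        positives.to_csv(out / "positives_stratified.csv", index=False)
        stage = "tto"
        records = onset_records(dataset)
        counts["onset_records"] = len(records)
        counts["onset_included"] = sum(r.included for r in records)
        per_drug = tto_summary_table(records, min_n=config.min_tto_n)
        per_drug.to_csv(out / "tto_by_drug.csv", index=False)
        atc1 = {
            row["INGREDIENT"]: row["ATC1"] or "unmapped"
            for _, row in dataset.mentions.drop_duplicates("INGREDIENT").iterrows()
        }
        per_atc = tto_summary_table(records, by=atc1, min_n=config.min_tto_n)
        per_atc.to_csv(out / "tto_by_atc1.csv", index=False)
        groups = {}
        for r in records:
            if r.included:
                groups.setdefault(atc1.get(r.drug, "unmapped"), []).append(r.tto_days)
        groups = {k: v for k, v in groups.items() if v}
        if len(groups) >= 2:
            curves = cumulative_incidence(groups)
            curves.to_csv(out / "cuminc_by_atc1.csv", index=False)
            stat, df_, p = logrank_test(groups)
            counts["logrank"] = {"statistic": stat, "df": df_, "p": p}
        stage = "descriptives"
        summarize(dataset).to_csv(out / "table1.csv", index=False)
        annual_series(dataset).to_csv(out / "annual_series.csv", index=False)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "stage_counts": counts,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    logger.info("pipeline complete: %s", out)
    return out


def simulate_to_dir(config: SyntheticConfig, directory: Path | str) -> Path:
    """Generate a synthetic quarter, write tables + ground truth to disk."""
    tables, truth = generate(config)
    directory = Path(directory)
    write_quarter(tables, directory)
    truth.to_json(directory / "ground_truth.json")
    config.to_yaml(directory / "synthetic_config.yaml")
    return directory
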