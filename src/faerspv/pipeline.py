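"""End-to-end orchestration: ingest → link → dedup → filter → tables → scans.

The run is driven by a :class:`RunConfig` (YAML-loadable), executes its
stages in a fixed order, and writes every table plus a deterministic JSON
manifest, so reruns with identical inputs and seed produce byte-identical
outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Sequence

from . import __version__, faers_io
from .cohort_builder import filter_adolescent
from .descriptive_stats import (
    drug_drilldown,
    frequency_table,
    load_gene_annotations,
    rank_genes,
    write_frequency_csv,
)
from .disproportionality import ALL_ROLES, SUSPECT_ROLES, scan_drugs, write_scan_csv
from .synthetic_faers import SyntheticConfig, config_from_dict, generate, write_truth_table

logger = logging.getLogger(__name__)

DEFAULT_CASE_PTS = ("Hyperglycaemia", "Pneumothorax", "Completed suicide", "Drug interaction")
DEFAULT_CONTROL_PT = "Diarrhoea"


class ConfigError(ValueError):
    """Invalid run configuration (CLI exit code 1)."""


class StageError(RuntimeError):
    """A pipeline stage failed (CLI exit code 2)."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    out_dir: str = "faerspv_out"
    quarters: list[dict] = field(default_factory=list)  # [{"label": ..., "dir": ...}]
    synthetic: dict | None = None  # SyntheticConfig fields; used when no quarters given
    age_min_years: float = 12.0
    age_max_years_exclusive: float = 18.0
    admit_age_group_code: bool = False
    control_pt: str = DEFAULT_CONTROL_PT
    case_pts: Sequence[str] = DEFAULT_CASE_PTS
    top_n_tables: int = 15
    top_n_scan: int = 20
    drug_roles: str = "all"  # "all" or "suspect"
    denominator_note: str = "cohort tables use n_cases; drill-downs use mentions"
    drilldown_drug: str | None = None  # default: most frequent drug
    gene_annotations: str | None = None
    gene_drugs: Sequence[str] = ()
    seed: int = 0

    def validate(self) -> None:
        control = self.control_pt.casefold()
        if any(pt.casefold() == control for pt in self.case_pts):
            raise ConfigError(f"control PT {self.control_pt!r} must not be among the case PTs")
        if self.top_n_tables < 1 or self.top_n_scan < 1:
            raise ConfigError("top_n values must be >= 1")
        if self.age_min_years >= self.age_max_years_exclusive:
            raise ConfigError("age_min_years must be < age_max_years_exclusive")
        if self.drug_roles not in ("all", "suspect"):
            raise ConfigError("drug_roles must be 'all' or 'suspect'")
        if not self.quarters and self.synthetic is None:
            raise ConfigError("provide either quarters or a synthetic block")

    @property
    def roles(self):
        return SUSPECT_ROLES if self.drug_roles == "suspect" else ALL_ROLES


def load_config(path: str | Path) -> RunConfig:
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError(f"config file {path} must contain a mapping")
    try:
        cfg = RunConfig(**data)
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc
    cfg.validate()
    return cfg


def _canonical(obj):
    if isinstance(obj, dict):
        return {str(k): _canonical(v) for k, v in sorted(obj.items(), key=lambda kv: str(kv[0]))}
    if isinstance(obj, (list, tuple)):
        return [_canonical(v) for v in obj]
    return obj


def _config_hash(config: RunConfig) -> str:
    data = asdict(config)
    data.pop("out_dir")  # output location is not an analytic input
    payload = json.dumps(_canonical(data), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _slug(pt: str) -> str:
    return "".join(ch if ch.isalnum() else "_" for ch in pt.strip().casefold())


def load_cases(config: RunConfig, out_dir: Path, manifest: dict) -> list[faers_io.CaseReport]:
    """Resolve inputs (synthetic or on-disk quarters), read and link."""
    quarters = list(config.quarters)
    if not quarters:
        syn = dict(config.synthetic or {})
        syn.setdefault("seed", config.seed)
        syn_cfg = config_from_dict(syn)
        syn_dir = out_dir / "synthetic"
        generate(syn_cfg, syn_dir)
        write_truth_table(syn_cfg, syn_dir / "truth_table.csv")
        quarters = [{"label": syn_cfg.quarter_label, "dir": str(syn_dir)}]
        manifest["synthetic"] = {"n_cases": syn_cfg.n_cases, "seed": syn_cfg.seed}

    cases: list[faers_io.CaseReport] = []
    reports = {}
    n_demo_rows = 0
    for entry in quarters:
        label = entry.get("label", Path(entry["dir"]).name)
        paths = entry.get("paths") or faers_io.discover_quarter(entry["dir"], label)
        quarter = faers_io.read_quarter(paths, label)
        linked = faers_io.link_tables(quarter)
        n_demo_rows += quarter.parse_report.rows_read["DEMO"]
        cases.extend(linked)
        reports[label] = json.loads(quarter.parse_report.to_json())
        logger.info("ingested quarter %s: %d linked cases", label, len(linked))
    (out_dir / "parse_report.json").write_text(json.dumps(reports, indent=2, sort_keys=True) + "\n")
    manifest["stages"]["ingest_demo_rows"] = n_demo_rows
    manifest["stages"]["linked_cases"] = len(cases)
    manifest["outputs"].append("parse_report.json")
    return cases


def run(config: RunConfig) -> dict:
    """Execute the full analysis; returns (and writes) the run manifest."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "package_version": __version__,
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "stages": {},
        "outputs": [],
        "frequency_tables": [],
        "scans": [],
    }

    stage = "ingest"
    try:
        cases = load_cases(config, out_dir, manifest)

        stage = "deduplicate"
        deduped = faers_io.deduplicate(cases)
        manifest["stages"]["deduplicated_cases"] = len(deduped)
        logger.info("deduplicated: %d -> %d cases", len(cases), len(deduped))

        stage = "filter"
        cohort = filter_adolescent(
            deduped,
            min_years=config.age_min_years,
            max_years_exclusive=config.age_max_years_exclusive,
            admit_age_group_code=config.admit_age_group_code,
        )
        manifest["stages"]["cohort_cases"] = cohort.n_cases
        cohort.summary_json(out_dir / "cohort_summary.json")
        manifest["outputs"].append("cohort_summary.json")
        logger.info("cohort: %d cases in [%s, %s)", cohort.n_cases,
                    config.age_min_years, config.age_max_years_exclusive)

        stage = "frequency_tables"
        drug_rows = frequency_table(cohort, "drug", config.top_n_tables)
        for dimension, rows in (
            ("drug", drug_rows),
            ("reaction", frequency_table(cohort, "reaction", config.top_n_tables)),
            ("indication", frequency_table(cohort, "indication", config.top_n_tables)),
        ):
            name = f"freq_{dimension}.csv"
            write_frequency_csv(rows, out_dir / name)
            manifest["frequency_tables"].append(name)
            manifest["outputs"].append(name)

        stage = "drilldown"
        target = config.drilldown_drug or (drug_rows[0].item if drug_rows else None)
        if target:
            reac_rows, indi_rows = drug_drilldown(cohort, target, config.top_n_tables)
            write_frequency_csv(reac_rows, out_dir / "drilldown_reactions.csv")
            write_frequency_csv(indi_rows, out_dir / "drilldown_indications.csv")
            manifest["drilldown_drug"] = target
            manifest["outputs"] += ["drilldown_reactions.csv", "drilldown_indications.csv"]

        stage = "scans"
        scan_drug_list = [
            r.item for r in frequency_table(cohort, "drug", config.top_n_scan)
        ]
        for case_pt in config.case_pts:
            results = scan_drugs(cohort, case_pt, config.control_pt, scan_drug_list,
                                 roles=config.roles)
            name = f"scan_{_slug(case_pt)}.csv"
            write_scan_csv(results, out_dir / name)
            manifest["scans"].append(name)
            manifest["outputs"].append(name)
            logger.info("scan %s vs %s: %d drugs", case_pt, config.control_pt, len(results))

        stage = "gene_ranking"
        if config.gene_annotations:
            annotations = load_gene_annotations(config.gene_annotations)
            ranking = {
                drug: [{"gene": a.gene, "score": a.score} for a in rank_genes(drug, annotations)]
                for drug in (config.gene_drugs or sorted({a.drug for a in annotations}))
            }
            (out_dir / "gene_ranking.json").write_text(
                json.dumps(ranking, indent=2, sort_keys=True) + "\n"
            )
            manifest["outputs"].append("gene_ranking.json")
    except ConfigError:
        raise
    except Exception as exc:  # noqa: BLE001 — stage name is part of the contract
        raise StageError(stage, exc) from exc

    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
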