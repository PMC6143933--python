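"""Seeded generator of FAERS-dialect quarters with injected signals.

The sampling model is shared between :func:`generate` (which writes the
seven "$"-delimited tables to disk) and :func:`sample_cohort` (which
returns linked :class:`~faerspv.faers_io.CaseReport` objects directly, for
fast statistical replicates): both call :func:`_sample_core`, so the truth
table emitted by :func:`truth_table` describes either route.

Event model — for each case and each catalog event PT::

    logit P(event) = logit(baseline) + sum over exposed drugs of log-OR

with events independent given exposures.  Because the designated-control
design conditions on (case XOR control) and the control PT carries no
signal, the population cross-ratio recovered downstream equals the injected
odds ratio exactly.

Cases that would sample zero drugs receive a filler concomitant, and cases
with zero events receive a filler PT; both fillers live *outside* the
catalogs so catalog marginals and injected signals are untouched.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import expit, logit

from .cohort_builder import Cohort
from .faers_io import TABLE_KINDS, CaseReport, DrugEntry, write_table

FILLER_DRUG = "MULTIVITAMINS"
FILLER_REACTION = "Drug ineffective"

DEFAULT_INDICATIONS = (
    "Schizophrenia",
    "Attention deficit/hyperactivity disorder",
    "Depression",
    "Pain",
    "Epilepsy",
    "Product used for unknown indication",
)

#: (unit code, low years, high years, weight) — straddles the 12–18 window
#: and exercises every supported unit.
DEFAULT_AGE_MIXTURE = (
    ("YR", 12.0, 18.0, 0.45),
    ("YR", 18.0, 40.0, 0.15),
    ("MON", 6.0, 12.0, 0.15),
    ("DEC", 12.0, 18.0, 0.10),
    ("WK", 12.0, 18.0, 0.05),
    ("DY", 0.1, 12.0, 0.05),
    ("HR", 0.0, 0.1, 0.05),
)

#: years-per-unit divisors for encoding sampled ages into FAERS columns
_UNIT_FROM_YEARS = {
    "DEC": 0.1, "YR": 1.0, "MON": 12.0, "WK": 52.1775, "DY": 365.25, "HR": 8766.0,
}

_HEADERS = {
    "DEMO": ["primaryid", "caseid", "caseversion", "i_f_code", "event_dt", "fda_dt",
             "rept_cod", "age", "age_cod", "age_grp", "sex", "wt", "wt_cod",
             "occp_cod", "reporter_country", "occr_country"],
    "DRUG": ["primaryid", "caseid", "drug_seq", "role_cod", "drugname", "prod_ai",
             "route", "dose_vbm", "dechal", "rechal"],
    "REAC": ["primaryid", "caseid", "pt", "drug_rec_act"],
    "OUTC": ["primaryid", "caseid", "outc_cod"],
    "RPSR": ["primaryid", "caseid", "rpsr_cod"],
    "THER": ["primaryid", "caseid", "dsg_drug_seq", "start_dt", "end_dt", "dur", "dur_cod"],
    "INDI": ["primaryid", "caseid", "indi_drug_seq", "indi_pt"],
}


class SyntheticConfigError(ValueError):
    """Raised for invalid generator configurations (before any file I/O)."""


@dataclass
class SyntheticConfig:
    n_cases: int = 1000
    seed: int = 0
    age_mixture: Sequence[tuple[str, float, float, float]] = DEFAULT_AGE_MIXTURE
    sex_probs: tuple[float, float, float] = (0.48, 0.48, 0.04)  # male, female, undefined
    drug_catalog: Sequence[tuple[str, float]] = (
        ("RISPERIDONE", 0.30),
        ("QUETIAPINE FUMARATE", 0.20),
        ("IBUPROFEN", 0.15),
        ("METHOTREXATE", 0.10),
        ("ONDANSETRON HYDROCHLORIDE", 0.08),
    )
    event_catalog: Sequence[tuple[str, float]] = (
        ("Diarrhoea", 0.20),
        ("Hyperglycaemia", 0.10),
        ("Pneumothorax", 0.05),
        ("Completed suicide", 0.05),
        ("Drug interaction", 0.08),
    )
    signal_matrix: dict[tuple[str, str], float] = field(default_factory=dict)
    duplicate_rate: float = 0.0
    both_event_rate: float = 0.0
    indication_catalog: Sequence[str] = DEFAULT_INDICATIONS
    quarter_label: str = "2017q3"

    def validate(self) -> None:
        if self.n_cases < 1:
            raise SyntheticConfigError("n_cases must be >= 1")
        if abs(sum(self.sex_probs) - 1.0) > 1e-9 or any(p < 0 for p in self.sex_probs):
            raise SyntheticConfigError("sex_probs must be a simplex")
        weights = [w for _, _, _, w in self.age_mixture]
        if not weights or any(w < 0 for w in weights) or sum(weights) <= 0:
            raise SyntheticConfigError("age_mixture weights must be nonnegative and sum > 0")
        for unit, lo, hi, _ in self.age_mixture:
            if unit not in _UNIT_FROM_YEARS:
                raise SyntheticConfigError(f"unknown age unit code {unit!r}")
            if not 0 <= lo <= hi:
                raise SyntheticConfigError(f"bad age band [{lo}, {hi}]")
        for name, p in self.drug_catalog:
            if not name or not 0 <= p <= 1:
                raise SyntheticConfigError(f"bad drug catalog entry ({name!r}, {p})")
        for pt, p in self.event_catalog:
            if not pt or not 0 < p < 1:
                raise SyntheticConfigError(f"bad event catalog entry ({pt!r}, {p})")
        drug_names = {name for name, _ in self.drug_catalog}
        event_pts = {pt for pt, _ in self.event_catalog}
        for (drug, pt), beta in self.signal_matrix.items():
            if drug not in drug_names:
                raise SyntheticConfigError(f"signal references unknown drug {drug!r}")
            if pt not in event_pts:
                raise SyntheticConfigError(f"signal references unknown event {pt!r}")
            if not math.isfinite(beta):
                raise SyntheticConfigError(f"non-finite log-OR for ({drug}, {pt})")
        if not 0 <= self.duplicate_rate < 1:
            raise SyntheticConfigError("duplicate_rate must be in [0, 1)")
        if not 0 <= self.both_event_rate < 1:
            raise SyntheticConfigError("both_event_rate must be in [0, 1)")
        if self.both_event_rate > 0 and len(self.event_catalog) < 2:
            raise SyntheticConfigError("both_event_rate needs >= 2 catalog events")


def _sample_core(config: SyntheticConfig, rng: np.random.Generator) -> dict:
    """Draw the latent case-level structure (vectorized).

    Returns arrays: age_years, age_unit index, sex code index, exposure
    (n x n_drugs bool), events (n x n_events bool), duplicated (n bool).
    """
    n = config.n_cases
    # ages
    weights = np.array([w for *_, w in config.age_mixture], dtype=float)
    weights /= weights.sum()
    band = rng.choice(len(weights), size=n, p=weights)
    lo = np.array([b[1] for b in config.age_mixture])
    hi = np.array([b[2] for b in config.age_mixture])
    age_years = lo[band] + rng.random(n) * (hi[band] - lo[band])
    # sex
    sex_idx = rng.choice(3, size=n, p=np.asarray(config.sex_probs, dtype=float))
    # exposures — independent Bernoulli per catalog drug
    prev = np.array([p for _, p in config.drug_catalog], dtype=float)
    exposure = rng.random((n, len(prev))) < prev
    # events — logistic in exposures
    base = np.array([p for _, p in config.event_catalog], dtype=float)
    beta = np.zeros((len(prev), len(base)))
    drug_index = {name: i for i, (name, _) in enumerate(config.drug_catalog)}
    event_index = {pt: j for j, (pt, _) in enumerate(config.event_catalog)}
    for (drug, pt), b in config.signal_matrix.items():
        beta[drug_index[drug], event_index[pt]] = b
    eta = logit(base)[None, :] + exposure.astype(float) @ beta
    events = rng.random((n, len(base))) < expit(eta)
    if config.both_event_rate > 0:
        forced = rng.random(n) < config.both_event_rate
        events[forced, 0] = True
        events[forced, 1] = True
    duplicated = rng.random(n) < config.duplicate_rate
    return {
        "age_years": age_years,
        "age_unit": band,
        "sex_idx": sex_idx,
        "exposure": exposure,
        "events": events,
        "duplicated": duplicated,
    }


_SEX_CODES = ("M", "F", "")
_SEX_NAMES = ("male", "female", "undefined")


def _case_drug_names(config: SyntheticConfig, exposure_row: np.ndarray) -> list[str]:
    names = [config.drug_catalog[j][0] for j in np.flatnonzero(exposure_row)]
    return names or [FILLER_DRUG]


def _case_reactions(config: SyntheticConfig, event_row: np.ndarray) -> list[str]:
    pts = [config.event_catalog[j][0] for j in np.flatnonzero(event_row)]
    return pts or [FILLER_REACTION]


def generate(config: SyntheticConfig, out_dir: str | Path) -> dict[str, Path]:
    """Write one synthetic quarter (all seven tables) to ``out_dir``.

    Fully reproducible from ``config.seed``: identical configs give
    byte-identical files.  Duplicate cases are emitted as an extra
    caseversion-2 report with a later receipt date.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    core = _sample_core(config, rng)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    rows: dict[str, list[dict[str, str]]] = {kind: [] for kind in TABLE_KINDS}
    n_indi = len(config.indication_catalog)
    for i in range(config.n_cases):
        caseid = str(1000001 + i)
        unit_code = config.age_mixture[core["age_unit"][i]][0]
        age_in_unit = core["age_years"][i] * _UNIT_FROM_YEARS[unit_code]
        sex_code = _SEX_CODES[core["sex_idx"][i]]
        drug_names = _case_drug_names(config, core["exposure"][i])
        reactions = _case_reactions(config, core["events"][i])
        versions = [("1", "20170815")]
        if core["duplicated"][i]:
            versions.append(("2", "20170920"))
        for version, fda_dt in versions:
            pid = caseid + version  # primaryid = caseid*10 + caseversion
            rows["DEMO"].append({
                "primaryid": pid, "caseid": caseid, "caseversion": version,
                "i_f_code": "I" if version == "1" else "F",
                "event_dt": "20170701", "fda_dt": fda_dt, "rept_cod": "EXP",
                "age": f"{age_in_unit:.2f}", "age_cod": unit_code, "age_grp": "",
                "sex": sex_code, "wt": "", "wt_cod": "", "occp_cod": "MD",
                "reporter_country": "US", "occr_country": "US",
            })
            for seq, name in enumerate(drug_names, start=1):
                role = "PS" if seq == 1 else ("SS", "C", "I")[(i + seq) % 3]
                rows["DRUG"].append({
                    "primaryid": pid, "caseid": caseid, "drug_seq": str(seq),
                    "role_cod": role, "drugname": name, "prod_ai": name,
                    "route": "Oral", "dose_vbm": "", "dechal": "", "rechal": "",
                })
                rows["THER"].append({
                    "primaryid": pid, "caseid": caseid, "dsg_drug_seq": str(seq),
                    "start_dt": "20170601", "end_dt": "", "dur": "", "dur_cod": "",
                })
                rows["INDI"].append({
                    "primaryid": pid, "caseid": caseid, "indi_drug_seq": str(seq),
                    "indi_pt": config.indication_catalog[(i + seq) % n_indi],
                })
            for pt in reactions:
                rows["REAC"].append({"primaryid": pid, "caseid": caseid, "pt": pt, "drug_rec_act": ""})
            if i % 3 == 0:
                rows["OUTC"].append({"primaryid": pid, "caseid": caseid,
                                     "outc_cod": ("HO", "OT", "LT")[i % 3]})
            rows["RPSR"].append({"primaryid": pid, "caseid": caseid,
                                 "rpsr_cod": ("FGN", "HP", "CSM")[i % 3]})

    paths = {}
    for kind in TABLE_KINDS:
        path = out_dir / f"{kind}{config.quarter_label}.txt"
        write_table(path, _HEADERS[kind], rows[kind])
        paths[kind] = path
    return paths


def sample_cohort(config: SyntheticConfig, rng: np.random.Generator | None = None) -> Cohort:
    """Draw one deduplicated cohort of linked CaseReports directly (no file
    round-trip) from the same sampling model as :func:`generate`.

    Intended for simulation studies where thousands of replicate cohorts
    are needed; duplicate emission is skipped (dedup would remove the extra
    versions anyway).
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    core = _sample_core(config, rng)
    n_indi = len(config.indication_catalog)
    cases = []
    for i in range(config.n_cases):
        caseid = str(1000001 + i)
        drug_names = _case_drug_names(config, core["exposure"][i])
        drugs = [
            DrugEntry(
                verbatim_name=name, normalized_name=name,
                role="primary_suspect" if seq == 1 else
                     ("secondary_suspect", "concomitant", "interacting")[(i + seq) % 3],
                indication=config.indication_catalog[(i + seq) % n_indi],
            )
            for seq, name in enumerate(drug_names, start=1)
        ]
        cases.append(
            CaseReport(
                primaryid=caseid + "1",
                caseid=caseid,
                caseversion=1,
                receipt_date=None,
                age_years=float(core["age_years"][i]),
                sex=_SEX_NAMES[core["sex_idx"][i]],
                drugs=drugs,
                reactions=_case_reactions(config, core["events"][i]),
                indications=[d.indication for d in drugs if d.indication],
            )
        )
    return Cohort(cases=cases, filters={"synthetic": True, "seed": config.seed, "n_cases": config.n_cases})


def truth_table(config: SyntheticConfig) -> list[tuple[str, str, float]]:
    """Every (drug, event PT) catalog pair with its injected log-OR (0.0
    for pairs not in the signal matrix)."""
    config.validate()
    return [
        (drug, pt, float(config.signal_matrix.get((drug, pt), 0.0)))
        for drug, _ in config.drug_catalog
        for pt, _ in config.event_catalog
    ]


def write_truth_table(config: SyntheticConfig, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["drug", "event_pt", "true_log_or"])
        for drug, pt, beta in truth_table(config):
            writer.writerow([drug, pt, f"{beta:.6g}"])


def config_from_dict(data: dict) -> SyntheticConfig:
    """Build a config from parsed YAML/JSON; signal matrix entries are
    lists ``[drug, event_pt, log_or]``."""
    data = dict(data)
    if "signal_matrix" in data and not isinstance(data["signal_matrix"], dict):
        data["signal_matrix"] = {(d, pt): float(b) for d, pt, b in data["signal_matrix"]}
    if "age_mixture" in data:
        data["age_mixture"] = [tuple(band) for band in data["age_mixture"]]
    if "sex_probs" in data:
        data["sex_probs"] = tuple(data["sex_probs"])
    if "drug_catalog" in data:
        data["drug_catalog"] = [tuple(x) for x in data["drug_catalog"]]
    if "event_catalog" in data:
        data["event_catalog"] = [tuple(x) for x in data["event_catalog"]]
    cfg = SyntheticConfig(**data)
    cfg.validate()
    return cfg
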