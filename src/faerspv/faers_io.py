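"""Reading, linking and deduplication of FAERS quarterly ASCII tables.

FAERS quarters ship as seven "$"-delimited text tables (DEMO, DRUG, REAC,
OUTC, RPSR, THER, INDI) keyed on ``primaryid``.  A case (``caseid``) may be
present in several versions (``caseversion``); one report version is one
``primaryid``.  This module reads the raw tables into :class:`RawQuarter`,
links child tables onto DEMO rows to build :class:`CaseReport` objects and
collapses case versions with :func:`deduplicate`.

Files are decoded as Latin-1 with replacement (legacy quarters are not
UTF-8 clean).  Column-name variants across quarters (e.g. ``gndr_cod`` vs
``sex``) are folded through an alias map.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path
from typing import Iterable, Mapping, Sequence

DELIMITER = "$"
ENCODING = "latin-1"

TABLE_KINDS = ("DEMO", "DRUG", "REAC", "OUTC", "RPSR", "THER", "INDI")

#: Pre-/post-dialect column-name variants, folded to the modern name.
COLUMN_ALIASES = {
    "gndr_cod": "sex",
    "outc_code": "outc_cod",
    "isr": "primaryid",
    "case": "caseid",
    "case_id": "caseid",
}

#: Recognized (modern) column names per table kind; a header containing a
#: name outside this set (after aliasing) is rejected as an unknown dialect.
KNOWN_COLUMNS: dict[str, frozenset[str]] = {
    "DEMO": frozenset(
        """primaryid caseid caseversion i_f_code i_f_cod event_dt mfr_dt
        init_fda_dt fda_dt rept_cod auth_num mfr_num mfr_sndr lit_ref age
        age_cod age_grp sex e_sub wt wt_cod rept_dt to_mfr occp_cod
        reporter_country occr_country death_dt confid foll_seq image""".split()
    ),
    "DRUG": frozenset(
        """primaryid caseid drug_seq role_cod drugname prod_ai val_vbm route
        dose_vbm cum_dose_chr cum_dose_unit dechal rechal lot_num exp_dt
        nda_num dose_amt dose_unit dose_form dose_freq""".split()
    ),
    "REAC": frozenset("primaryid caseid pt drug_rec_act".split()),
    "OUTC": frozenset("primaryid caseid outc_cod".split()),
    "RPSR": frozenset("primaryid caseid rpsr_cod".split()),
    "THER": frozenset(
        "primaryid caseid dsg_drug_seq drug_seq start_dt end_dt dur dur_cod".split()
    ),
    "INDI": frozenset("primaryid caseid indi_drug_seq drug_seq indi_pt".split()),
}

REQUIRED_COLUMNS: dict[str, frozenset[str]] = {
    "DEMO": frozenset(["primaryid", "caseid", "caseversion", "fda_dt", "age", "age_cod", "sex"]),
    "DRUG": frozenset(["primaryid", "drugname", "role_cod"]),
    "REAC": frozenset(["primaryid", "pt"]),
    "OUTC": frozenset(["primaryid", "outc_cod"]),
    "RPSR": frozenset(["primaryid", "rpsr_cod"]),
    "THER": frozenset(["primaryid"]),
    "INDI": frozenset(["primaryid", "indi_pt"]),
}

ROLE_CODES = {
    "PS": "primary_suspect",
    "SS": "secondary_suspect",
    "C": "concomitant",
    "I": "interacting",
}

SEX_CODES = {"M": "male", "F": "female"}


class FaersIOError(ValueError):
    """Raised for missing files or unrecognized table dialects."""


@dataclass
class ParseReport:
    """Row-level accounting for one ingestion run.

    Invariant: for every child table, ``rows_read = attached + orphaned +
    dropped_bad_field_count + rows_of_excluded_cases``.
    """

    rows_read: dict[str, int] = field(default_factory=dict)
    rows_dropped: dict[str, int] = field(default_factory=dict)
    orphan_rows: dict[str, int] = field(default_factory=dict)
    attached_rows: dict[str, int] = field(default_factory=dict)
    excluded_case_rows: dict[str, int] = field(default_factory=dict)
    cases_excluded_no_reactions: int = 0
    cases_excluded_no_drugs: int = 0
    drug_entries_dropped_empty_name: int = 0

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(self.__dict__, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(payload + "\n")
        return payload


@dataclass
class RawQuarter:
    """One quarter's seven tables as ordered field maps.

    ``headers[kind]`` records the (alias-normalized) column order used on
    disk so a quarter can be re-serialized losslessly.
    """

    quarter_label: str
    tables: dict[str, list[dict[str, str]]]
    headers: dict[str, list[str]]
    parse_report: ParseReport = field(default_factory=ParseReport)

    def __post_init__(self) -> None:
        for kind in TABLE_KINDS:
            self.tables.setdefault(kind, [])
            self.headers.setdefault(kind, sorted(REQUIRED_COLUMNS[kind]))


@dataclass
class DrugEntry:
    verbatim_name: str
    normalized_name: str
    role: str  # primary_suspect | secondary_suspect | concomitant | interacting
    indication: str | None = None


@dataclass
class CaseReport:
    """One report version, fully linked across the seven tables."""

    primaryid: str
    caseid: str
    caseversion: int
    receipt_date: dt.date | None
    age_years: float | None
    sex: str  # male | female | undefined
    drugs: list[DrugEntry]
    reactions: list[str]
    indications: list[str] = field(default_factory=list)
    outcomes: list[str] = field(default_factory=list)
    sources: list[str] = field(default_factory=list)
    age_group: str = ""

    @cached_property
    def drug_names(self) -> frozenset[str]:
        """Normalized drug names (cached: reports are treated as immutable
        once linked)."""
        return frozenset(d.normalized_name for d in self.drugs)

    @cached_property
    def reaction_set(self) -> frozenset[str]:
        """Case-folded reaction PTs for case-insensitive matching (cached)."""
        return frozenset(r.casefold() for r in self.reactions)


def normalize_drug_name(verbatim: str, synonym_map: Mapping[str, str] | None = None) -> str:
    """Uppercase, trim and collapse internal whitespace; optionally map
    through a synonym table.  Salt forms are *not* stripped: "QUETIAPINE
    FUMARATE" stays distinct from "QUETIAPINE" unless a synonym map says
    otherwise.
    """
    name = " ".join(verbatim.upper().split())
    if synonym_map:
        name = synonym_map.get(name, name)
    return name


def _normalize_header(kind: str, raw_header: Sequence[str]) -> list[str]:
    cols = [COLUMN_ALIASES.get(c.strip().lower(), c.strip().lower()) for c in raw_header]
    unknown = [c for c in cols if c not in KNOWN_COLUMNS[kind]]
    if unknown:
        raise FaersIOError(
            f"{kind}: unrecognized columns {unknown!r}; known dialects expose "
            f"{sorted(KNOWN_COLUMNS[kind])}"
        )
    missing = REQUIRED_COLUMNS[kind] - set(cols)
    if missing:
        raise FaersIOError(f"{kind}: header missing required columns {sorted(missing)}")
    return cols


def read_table(path: str | Path, kind: str) -> tuple[list[str], list[dict[str, str]], int, int]:
    """Read one "$"-delimited table.

    Returns ``(header, rows, rows_read, rows_dropped)``; rows whose field
    count disagrees with the header are dropped and counted.
    """
    path = Path(path)
    if not path.exists():
        raise FaersIOError(f"{kind}: file not found: {path}")
    with open(path, encoding=ENCODING, errors="replace") as fh:
        header_line = fh.readline().rstrip("\r\n")
        if not header_line:
            raise FaersIOError(f"{kind}: empty file: {path}")
        header = _normalize_header(kind, header_line.split(DELIMITER))
        n_fields = len(header)
        rows: list[dict[str, str]] = []
        read = dropped = 0
        for line in fh:
            line = line.rstrip("\r\n")
            if not line:
                continue
            read += 1
            fields = line.split(DELIMITER)
            if len(fields) != n_fields:
                dropped += 1
                continue
            rows.append({col: val.strip() for col, val in zip(header, fields)})
    return header, rows, read, dropped


def read_quarter(paths: Mapping[str, str | Path], quarter_label: str) -> RawQuarter:
    """Read all seven tables of one quarter.

    ``paths`` maps table kind (DEMO/DRUG/...) to a file path.  Every kind
    must be present; a header-only file yields an empty table.
    """
    missing = [k for k in TABLE_KINDS if k not in paths]
    if missing:
        raise FaersIOError(f"missing table paths for kinds: {missing}")
    report = ParseReport()
    tables: dict[str, list[dict[str, str]]] = {}
    headers: dict[str, list[str]] = {}
    for kind in TABLE_KINDS:
        header, rows, read, dropped = read_table(paths[kind], kind)
        tables[kind] = rows
        headers[kind] = header
        report.rows_read[kind] = read
        report.rows_dropped[kind] = dropped
    return RawQuarter(quarter_label=quarter_label, tables=tables, headers=headers, parse_report=report)


def discover_quarter(directory: str | Path, quarter_label: str | None = None) -> dict[str, Path]:
    """Locate the seven table files in a directory by kind prefix
    (``DEMO*.txt`` etc., case-insensitive)."""
    directory = Path(directory)
    paths: dict[str, Path] = {}
    for kind in TABLE_KINDS:
        hits = sorted(
            p for p in directory.iterdir()
            if p.is_file() and p.name.upper().startswith(kind) and p.suffix.lower() in {".txt", ".tsv"}
        )
        if quarter_label:
            labeled = [p for p in hits if quarter_label.lower() in p.name.lower()]
            hits = labeled or hits
        if not hits:
            raise FaersIOError(f"{kind}: no file matching {kind}*.txt in {directory}")
        paths[kind] = hits[0]
    return paths


def write_table(path: str | Path, header: Sequence[str], rows: Iterable[Mapping[str, str]]) -> None:
    with open(path, "w", encoding=ENCODING, errors="replace", newline="\n") as fh:
        fh.write(DELIMITER.join(header) + "\n")
        for row in rows:
            fh.write(DELIMITER.join(row.get(col, "") for col in header) + "\n")


def write_quarter(q: RawQuarter, directory: str | Path) -> dict[str, Path]:
    """Serialize a RawQuarter back to the on-disk dialect (round-trip safe)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    for kind in TABLE_KINDS:
        path = directory / f"{kind}{q.quarter_label}.txt"
        write_table(path, q.headers[kind], q.tables[kind])
        paths[kind] = path
    return paths


def _parse_date(value: str) -> dt.date | None:
    value = value.strip()
    if len(value) == 8 and value.isdigit():
        try:
            return dt.date(int(value[:4]), int(value[4:6]), int(value[6:8]))
        except ValueError:
            return None
    return None


def _parse_caseversion(value: str) -> int:
    try:
        v = int(float(value))
    except (TypeError, ValueError):
        return 1
    return max(v, 1)


def link_tables(
    q: RawQuarter,
    synonym_map: Mapping[str, str] | None = None,
    report: ParseReport | None = None,
) -> list[CaseReport]:
    """Attach DRUG/REAC/INDI/OUTC/RPSR rows to their DEMO parent by exact
    ``primaryid`` match and emit one :class:`CaseReport` per DEMO row.

    Orphan child rows (no DEMO parent) are excluded and counted; cases that
    end up with zero drugs or zero reactions are excluded and counted —
    they cannot contribute to any frequency or 2x2 statistic.
    """
    from .cohort_builder import normalize_age  # local import avoids a module cycle

    if report is None:
        report = q.parse_report

    children: dict[str, dict[str, list[dict[str, str]]]] = {k: {} for k in TABLE_KINDS if k != "DEMO"}
    demo_ids = {row["primaryid"] for row in q.tables["DEMO"]}
    for kind in children:
        orphans = 0
        for row in q.tables[kind]:
            pid = row.get("primaryid", "")
            if pid in demo_ids:
                children[kind].setdefault(pid, []).append(row)
            else:
                orphans += 1
        report.orphan_rows[kind] = report.orphan_rows.get(kind, 0) + orphans
        report.attached_rows.setdefault(kind, 0)
        report.excluded_case_rows.setdefault(kind, 0)

    cases: list[CaseReport] = []
    for demo in q.tables["DEMO"]:
        pid = demo["primaryid"]
        kid_rows = {kind: children[kind].get(pid, []) for kind in children}

        drug_pairs: list[tuple[dict[str, str], DrugEntry]] = []
        seen_roles: set[tuple[str, str]] = set()
        for row in kid_rows["DRUG"]:
            name = normalize_drug_name(row.get("drugname", ""), synonym_map)
            if not name:
                report.drug_entries_dropped_empty_name += 1
                continue
            role = ROLE_CODES.get(row.get("role_cod", "").strip().upper(), "concomitant")
            if (name, role) in seen_roles:
                continue
            seen_roles.add((name, role))
            drug_pairs.append(
                (row, DrugEntry(verbatim_name=row.get("drugname", ""), normalized_name=name, role=role))
            )
        drugs = [entry for _, entry in drug_pairs]

        reactions = [row["pt"] for row in kid_rows["REAC"] if row.get("pt", "").strip()]
        if not drugs or not reactions:
            if not reactions:
                report.cases_excluded_no_reactions += 1
            else:
                report.cases_excluded_no_drugs += 1
            for kind in children:
                report.excluded_case_rows[kind] += len(kid_rows[kind])
            continue
        for kind in children:
            report.attached_rows[kind] += len(kid_rows[kind])

        indications = [row["indi_pt"] for row in kid_rows["INDI"] if row.get("indi_pt", "").strip()]
        # attach per-drug indications by drug_seq when both sides carry it
        seq_to_indi = {
            row.get("indi_drug_seq", row.get("drug_seq", "")): row["indi_pt"]
            for row in kid_rows["INDI"]
            if row.get("indi_pt", "").strip()
        }
        for drow, dentry in drug_pairs:
            seq = drow.get("drug_seq", "")
            if seq in seq_to_indi:
                dentry.indication = seq_to_indi[seq]

        age_years = normalize_age(demo.get("age", ""), demo.get("age_cod", ""))
        if age_years is not None and not (0 <= age_years <= 130):
            age_years = None
        cases.append(
            CaseReport(
                primaryid=pid,
                caseid=demo.get("caseid", pid),
                caseversion=_parse_caseversion(demo.get("caseversion", "1")),
                receipt_date=_parse_date(demo.get("fda_dt", "")),
                age_years=age_years,
                sex=SEX_CODES.get(demo.get("sex", "").strip().upper(), "undefined"),
                drugs=drugs,
                reactions=reactions,
                indications=indications,
                outcomes=[row["outc_cod"] for row in kid_rows["OUTC"] if row.get("outc_cod", "").strip()],
                sources=[row["rpsr_cod"] for row in kid_rows["RPSR"] if row.get("rpsr_cod", "").strip()],
                age_group=demo.get("age_grp", ""),
            )
        )
    return cases


def deduplicate(cases: Sequence[CaseReport]) -> list[CaseReport]:
    """Keep one report per ``caseid``: highest ``caseversion``, ties broken
    by latest receipt date, then lexicographically highest ``primaryid``.
    Applied across all pooled quarters.  Output sorted by caseid.
    """
    best: dict[str, CaseReport] = {}
    for case in cases:
        key = (case.caseversion, case.receipt_date or dt.date.min, case.primaryid)
        incumbent = best.get(case.caseid)
        if incumbent is None:
            best[case.caseid] = case
            continue
        inc_key = (incumbent.caseversion, incumbent.receipt_date or dt.date.min, incumbent.primaryid)
        if key > inc_key:
            best[case.caseid] = case
    return [best[cid] for cid in sorted(best)]
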