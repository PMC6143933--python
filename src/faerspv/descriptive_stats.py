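"""Frequency tables, per-drug drill-downs and gene-annotation ranking.

Two denominator conventions coexist deliberately:

- cohort-level tables (:func:`frequency_table`) divide by the number of
  cases in the cohort, so a row's pct reads "share of cases mentioning the
  item";
- drill-downs (:func:`drug_drilldown`) divide by the total number of
  distinct item mentions in the sub-cohort, so pcts across all items sum
  to 100.

Both are labeled in the output rather than guessed between.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from ._util import round_half_up
from .cohort_builder import Cohort, SexBreakdown, sex_breakdown
from .faers_io import CaseReport, normalize_drug_name

DIMENSIONS = ("drug", "reaction", "indication")


@dataclass
class FrequencyRow:
    item: str
    count: int
    sex: SexBreakdown
    pct: float
    denominator: int
    denominator_kind: str  # "cases" or "mentions"


@dataclass(frozen=True)
class GeneAnnotation:
    drug: str
    gene: str
    score: float


def _case_items(case: CaseReport, dimension: str) -> frozenset[str]:
    """Distinct items a case mentions in a dimension (within-case
    duplicates collapse to one)."""
    if dimension == "drug":
        return case.drug_names
    if dimension == "reaction":
        return frozenset(r.strip() for r in case.reactions if r.strip())
    if dimension == "indication":
        return frozenset(i.strip() for i in case.indications if i.strip())
    raise ValueError(f"unknown dimension {dimension!r}; expected one of {DIMENSIONS}")


def _tabulate(cases: Sequence[CaseReport], dimension: str) -> dict[str, list[CaseReport]]:
    by_item: dict[str, list[CaseReport]] = {}
    for case in cases:
        for item in _case_items(case, dimension):
            by_item.setdefault(item, []).append(case)
    return by_item


def frequency_table(cohort: Cohort, dimension: str, top_n: int) -> list[FrequencyRow]:
    """Top-N frequency table over the cohort, denominator = n_cases.

    Rows sort by count descending, ties alphabetically by item.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    by_item = _tabulate(cohort.cases, dimension)
    denom = cohort.n_cases
    rows = [
        FrequencyRow(
            item=item,
            count=len(members),
            sex=sex_breakdown(members),
            pct=round_half_up(100.0 * len(members) / denom, 2) if denom else 0.0,
            denominator=denom,
            denominator_kind="cases",
        )
        for item, members in by_item.items()
    ]
    rows.sort(key=lambda r: (-r.count, r.item))
    return rows[:top_n]


def drug_drilldown(
    cohort: Cohort, drug: str, top_n: int
) -> tuple[list[FrequencyRow], list[FrequencyRow]]:
    """Reaction and indication tables over the sub-cohort of cases listing
    ``drug``; denominator = total distinct-mention count, so untruncated
    pcts sum to 100."""
    target = normalize_drug_name(drug)
    sub = [c for c in cohort.cases if target in c.drug_names]
    out = []
    for dimension in ("reaction", "indication"):
        by_item = _tabulate(sub, dimension)
        denom = sum(len(v) for v in by_item.values())
        rows = [
            FrequencyRow(
                item=item,
                count=len(members),
                sex=sex_breakdown(members),
                pct=round_half_up(100.0 * len(members) / denom, 2) if denom else 0.0,
                denominator=denom,
                denominator_kind="mentions",
            )
            for item, members in by_item.items()
        ]
        rows.sort(key=lambda r: (-r.count, r.item))
        out.append(rows[:top_n])
    return out[0], out[1]


def load_gene_annotations(path: str | Path) -> list[GeneAnnotation]:
    """Load a drug→gene relevance-score table from TSV with columns
    ``drug``, ``gene``, ``score`` (header required)."""
    df = pd.read_csv(path, sep="\t", dtype={"drug": str, "gene": str})
    required = {"drug", "gene", "score"}
    if not required.issubset(df.columns):
        raise ValueError(f"annotation TSV must have columns {sorted(required)}, got {list(df.columns)}")
    annotations = []
    seen: set[tuple[str, str]] = set()
    for rec in df.itertuples(index=False):
        score = float(rec.score)
        if not math.isfinite(score) or score < 0:
            raise ValueError(f"non-finite or negative score for ({rec.drug}, {rec.gene}): {rec.score}")
        key = (normalize_drug_name(rec.drug), rec.gene.strip())
        if key in seen:
            raise ValueError(f"duplicate (drug, gene) pair: {key}")
        seen.add(key)
        annotations.append(GeneAnnotation(drug=key[0], gene=key[1], score=score))
    return annotations


def rank_genes(drug: str, annotations: Sequence[GeneAnnotation], k: int = 10) -> list[GeneAnnotation]:
    """The k highest-scoring genes annotated to ``drug``, score descending,
    ties by gene symbol ascending.  Unknown drug yields an empty list."""
    target = normalize_drug_name(drug)
    hits = [a for a in annotations if a.drug == target]
    hits.sort(key=lambda a: (-a.score, a.gene))
    return hits[:k]


def write_frequency_csv(rows: Sequence[FrequencyRow], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["item", "count", "male", "female", "undefined", "pct", "denominator", "denominator_kind"]
        )
        for r in rows:
            writer.writerow(
                [r.item, r.count, r.sex.n_male, r.sex.n_female, r.sex.n_undefined,
                 f"{r.pct:.2f}", r.denominator, r.denominator_kind]
            )
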