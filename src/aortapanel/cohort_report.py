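"""Cohort-level aggregation: diagnostic yield and FBN1 genotype-phenotype tables.

A proband is *positive* when at least one variant reaches likely pathogenic,
*VUS-only* when the best variant is a VUS, and *negative* otherwise.  The
genotype-phenotype table cross-tabulates the mutation class of each
FBN1-positive proband's causal variant against the aortic event, with
per-cell counts and mean ages, and rolls the truncating classes plus
splicing into a combined severity row.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import pandas as pd

from ._utils import round_half_up
from .acmg_classifier import PathogenicityTier
from .hgvs_consequence import MutationClass

logger = logging.getLogger(__name__)


class Diagnosis(str, Enum):
    MARFAN = "Marfan syndrome"
    SUSPECTED_MARFAN = "Suspected Marfan syndrome"
    SUSPECTED_LDS = "Suspected Loeys-Dietz syndrome"
    NON_SYNDROMIC = "Non-syndromic aortic events"


class AorticEvent(str, Enum):
    DISSECTION = "dissection"
    ANEURYSM = "aneurysm"  # prophylactic surgery for aneurysm
    VALVULAR = "valvular"  # valve replacement for severe valvular disease
    MILD_DILATION = "mild_dilation"
    UNKNOWN = "unknown"  # clinical information missing


class ProbandResult(str, Enum):
    POSITIVE = "positive"
    VUS_ONLY = "vus_only"
    NEGATIVE = "negative"


@dataclass(frozen=True)
class ClassifiedVariant:
    gene: str
    mutation_class: MutationClass
    tier: PathogenicityTier
    cdna: str | None = None


@dataclass
class Proband:
    id: str
    diagnosis: Diagnosis
    variants: list[ClassifiedVariant] = field(default_factory=list)
    sex: str | None = None
    aortic_event: AorticEvent = AorticEvent.UNKNOWN
    age_at_event: float | None = None

    def __post_init__(self) -> None:
        if self.aortic_event is AorticEvent.UNKNOWN and self.age_at_event is not None:
            raise ValueError(f"{self.id}: age given without a known aortic event")


def proband_result(p: Proband) -> ProbandResult:
    """Best-variant dominance: any (likely) pathogenic → positive."""
    best = max((v.tier for v in p.variants), default=PathogenicityTier.BENIGN)
    if best >= PathogenicityTier.LIKELY_PATHOGENIC:
        return ProbandResult.POSITIVE
    if best is PathogenicityTier.VUS:
        return ProbandResult.VUS_ONLY
    return ProbandResult.NEGATIVE


@dataclass
class CohortSummary:
    """Diagnosis × result cross-tab with totals and one-decimal percentages."""

    table: pd.DataFrame  # rows: diagnoses + Total; columns: cases/positive/vus_only/negative
    percentages: dict[str, float]  # of the Total row, one-decimal

    def __str__(self) -> str:
        return self.table.to_string()


def cohort_summary(cohort: Sequence[Proband]) -> CohortSummary:
    """Cross-tabulate diagnosis against genetic result over the whole cohort."""
    rows = []
    for p in cohort:
        rows.append({"diagnosis": p.diagnosis.value, "result": proband_result(p).value})
    df = pd.DataFrame(rows)
    order = [d.value for d in Diagnosis if d.value in set(df["diagnosis"])]
    ct = (
        pd.crosstab(df["diagnosis"], df["result"])
        .reindex(order)
        .reindex(columns=[r.value for r in ProbandResult], fill_value=0)
        .fillna(0)
        .astype(int)
    )
    ct.insert(0, "cases", ct.sum(axis=1))
    ct.loc["Total"] = ct.sum(axis=0)
    total = int(ct.loc["Total", "cases"])
    assert total == len(cohort)
    percentages = {
        r.value: round_half_up(100.0 * int(ct.loc["Total", r.value]) / total, 1)
        for r in ProbandResult
    }
    return CohortSummary(table=ct, percentages=percentages)


# ---------------------------------------------------------------------------
# FBN1 genotype-phenotype table


#: Row order of the genotype-phenotype table.
GP_CLASSES = [
    MutationClass.FRAMESHIFT_INSERTION,
    MutationClass.FRAMESHIFT_DELETION,
    MutationClass.STOPGAIN,
    MutationClass.SPLICING,
]
ROLLUP_ROW = "truncating_plus_splicing"
GP_EVENTS = [
    AorticEvent.DISSECTION,
    AorticEvent.ANEURYSM,
    AorticEvent.VALVULAR,
    AorticEvent.MILD_DILATION,
]

_SEVERITY = {  # most-severe-first tie-break for double-variant probands
    MutationClass.STOPGAIN: 0,
    MutationClass.FRAMESHIFT_DELETION: 1,
    MutationClass.FRAMESHIFT_INSERTION: 2,
    MutationClass.SPLICING: 3,
    MutationClass.STARTLOSS: 4,
    MutationClass.MISSENSE: 5,
    MutationClass.NONFRAMESHIFT_INDEL: 6,
}


@dataclass
class GenotypePhenotypeTable:
    counts: pd.DataFrame  # rows: classes + rollup + missense (+ other); cols: events
    mean_ages: pd.DataFrame  # same shape; NaN where count is 0 or no ages
    event_totals: dict[str, int]

    def cell(self, row: str, event: AorticEvent | str) -> tuple[int, float | None]:
        col = event.value if isinstance(event, AorticEvent) else event
        count = int(self.counts.loc[row, col])
        age = self.mean_ages.loc[row, col]
        return count, (None if pd.isna(age) else float(age))


def weighted_mean_age(cells: Iterable[tuple[int, float]]) -> float | None:
    """Count-weighted mean of per-cell mean ages, half-up to one decimal.

    Zero total count yields None rather than a number.
    """
    total = 0
    weighted = 0.0
    for count, mean in cells:
        if count < 0:
            raise ValueError("negative count")
        if count:
            total += count
            weighted += count * mean
    if total == 0:
        return None
    return round_half_up(weighted / total, 1)


def genotype_phenotype_table(probands: Sequence[Proband]) -> GenotypePhenotypeTable:
    """Cross-tabulate causal-FBN1 mutation class against aortic event.

    Each proband contributes one (likely) pathogenic FBN1 variant; a proband
    carrying two is counted once under the most severe class, with a warning.
    Probands without clinical information (event unknown) are excluded.
    Start-loss and non-frameshift indels fall into an ``other`` row rather
    than being forced into the four truncating/splicing classes.
    """
    contributions: list[tuple[str, AorticEvent, float | None]] = []
    for p in probands:
        if p.aortic_event is AorticEvent.UNKNOWN:
            continue
        causal = [
            v
            for v in p.variants
            if v.gene == "FBN1" and v.tier >= PathogenicityTier.LIKELY_PATHOGENIC
        ]
        if not causal:
            continue
        if len(causal) > 1:
            logger.warning("proband %s has %d causal FBN1 variants; counting the most severe", p.id, len(causal))
        chosen = min(causal, key=lambda v: _SEVERITY.get(v.mutation_class, 99))
        mc = chosen.mutation_class
        if mc in GP_CLASSES:
            row = mc.value
        elif mc is MutationClass.MISSENSE:
            row = "missense"
        else:
            row = "other"
        contributions.append((row, p.aortic_event, p.age_at_event))

    row_order = [mc.value for mc in GP_CLASSES] + [ROLLUP_ROW, "missense"]
    if any(r == "other" for r, _, _ in contributions):
        row_order.append("other")
    col_order = [e.value for e in GP_EVENTS]
    counts = pd.DataFrame(0, index=row_order, columns=col_order)
    ages = pd.DataFrame(float("nan"), index=row_order, columns=col_order)

    by_cell: dict[tuple[str, str], list[float]] = {}
    for row, event, age in contributions:
        counts.loc[row, event.value] += 1
        if age is not None:
            by_cell.setdefault((row, event.value), []).append(age)
    for (row, col), cell_ages in by_cell.items():
        ages.loc[row, col] = round_half_up(sum(cell_ages) / len(cell_ages), 1)

    # rollup of the four truncating/splicing classes
    sub = [mc.value for mc in GP_CLASSES]
    counts.loc[ROLLUP_ROW] = counts.loc[sub].sum(axis=0)
    for col in col_order:
        cells = [
            (int(counts.loc[r, col]), float(ages.loc[r, col]))
            for r in sub
            if int(counts.loc[r, col]) > 0 and not pd.isna(ages.loc[r, col])
        ]
        wm = weighted_mean_age(cells)
        ages.loc[ROLLUP_ROW, col] = float("nan") if wm is None else wm

    leaf_rows = [r for r in row_order if r != ROLLUP_ROW]
    event_totals = {
        col: int(counts.loc[leaf_rows, col].sum()) for col in col_order
    }
    return GenotypePhenotypeTable(counts=counts, mean_ages=ages, event_totals=event_totals)
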