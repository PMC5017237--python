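"""Five-tier pathogenicity classification with family-segregation reclassification.

The evidence axes follow clinical panel practice: prior literature report,
variant nature (null versus missense), population frequency, residue
conservation, in-silico predictions, de novo status, and family segregation.
The combining rule is a deterministic table (documented in docs/methods.md):

* MAF above 1% in any population database → benign, overriding everything;
* protein-null class (stopgain, frameshift, canonical ±1/±2 splice,
  start loss) absent from population databases → pathogenic;
* missense that destroys or creates an FBN1 cysteine, or any previously
  reported missense, absent from population databases → likely pathogenic;
* rare but present in a database with no supporting evidence → likely benign
  (conservation / in-silico support keeps it at VUS instead);
* a confirmed de novo occurrence promotes a VUS to likely pathogenic;
* everything else → VUS.

Family segregation is applied afterwards as a reclassification step: each
discordant observation (an affected relative who does not carry the variant,
or an unaffected relative who does) demotes the tier; strong concordance
promotes a VUS.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum, IntEnum
from typing import Mapping

from ._utils import parse_optional_float
from .hgvs_consequence import (
    NULL_CLASSES,
    CysteineInvolvement,
    MutationClass,
    classify_consequence,
    cysteine_involvement,
    parse_cdna,
    parse_protein,
)


class PathogenicityTier(IntEnum):
    """Ordered five-level classification."""

    BENIGN = 0
    LIKELY_BENIGN = 1
    VUS = 2
    LIKELY_PATHOGENIC = 3
    PATHOGENIC = 4

    @property
    def label(self) -> str:
        return {
            PathogenicityTier.BENIGN: "Benign",
            PathogenicityTier.LIKELY_BENIGN: "Likely Benign",
            PathogenicityTier.VUS: "VUS",
            PathogenicityTier.LIKELY_PATHOGENIC: "Likely Pathogenic",
            PathogenicityTier.PATHOGENIC: "Pathogenic",
        }[self]

    @classmethod
    def from_label(cls, text: str) -> "PathogenicityTier":
        key = text.strip().lower().replace("likey", "likely")
        mapping = {
            "benign": cls.BENIGN,
            "likely benign": cls.LIKELY_BENIGN,
            "vus": cls.VUS,
            "unknown significance": cls.VUS,
            "uncertain significance": cls.VUS,
            "likely pathogenic": cls.LIKELY_PATHOGENIC,
            "pathogenic": cls.PATHOGENIC,
        }
        if key not in mapping:
            raise ValueError(f"unknown pathogenicity label {text!r}")
        return mapping[key]


class PriorReport(str, Enum):
    FUNCTIONAL_STUDY = "functional_study"
    SEGREGATION_STUDY = "segregation_study"
    NONE = "none"


class DeNovoStatus(str, Enum):
    CONFIRMED = "confirmed"
    INHERITED_FROM_AFFECTED = "inherited_from_affected"
    INHERITED_FROM_UNAFFECTED = "inherited_from_unaffected"
    UNKNOWN = "unknown"


class EvidenceError(ValueError):
    pass


@dataclass(frozen=True)
class SegregationObservation:
    """Carrier status of tested relatives, split by affection status."""

    affected_tested: int = 0
    affected_carrying: int = 0
    unaffected_tested: int = 0
    unaffected_carrying: int = 0

    def __post_init__(self) -> None:
        for tested, carrying, group in (
            (self.affected_tested, self.affected_carrying, "affected"),
            (self.unaffected_tested, self.unaffected_carrying, "unaffected"),
        ):
            if tested < 0 or carrying < 0:
                raise EvidenceError(f"negative {group} count")
            if carrying > tested:
                raise EvidenceError(f"{group}: carrying {carrying} > tested {tested}")

    @property
    def total_tested(self) -> int:
        return self.affected_tested + self.unaffected_tested

    @property
    def affected_noncarriers(self) -> int:
        return self.affected_tested - self.affected_carrying

    @property
    def unaffected_carriers(self) -> int:
        return self.unaffected_carrying

    @property
    def discordant(self) -> int:
        """Observations arguing against pathogenicity."""
        return self.affected_noncarriers + self.unaffected_carriers


@dataclass(frozen=True)
class EvidenceSet:
    """Everything the classifier weighs for one variant."""

    gene: str
    variant_nature: MutationClass
    cysteine: CysteineInvolvement = CysteineInvolvement.NONE
    prior_report: PriorReport = PriorReport.NONE
    population_maf: float | None = None
    conservation_support: bool = False
    insilico_support: int = 0  # damaging predictions among the 3 consulted tools
    de_novo: DeNovoStatus = DeNovoStatus.UNKNOWN
    segregation: SegregationObservation | None = None

    def __post_init__(self) -> None:
        if self.population_maf is not None and not 0 <= self.population_maf <= 1:
            raise EvidenceError(f"population MAF {self.population_maf} outside [0, 1]")
        if not 0 <= self.insilico_support <= 3:
            raise EvidenceError("insilico_support must be within 0..3")


_DENOVO_TOKENS = {
    "de novo": DeNovoStatus.CONFIRMED,
    "denovo": DeNovoStatus.CONFIRMED,
    "inherited from affected": DeNovoStatus.INHERITED_FROM_AFFECTED,
    "inherited from unaffected": DeNovoStatus.INHERITED_FROM_UNAFFECTED,
}


def _parse_de_novo(token: str | None) -> DeNovoStatus:
    if token is None:
        return DeNovoStatus.UNKNOWN
    key = str(token).strip().lower()
    if key in _DENOVO_TOKENS:
        return _DENOVO_TOKENS[key]
    # "Inherited from mother/father" without the parent's affection status
    # cannot distinguish the two inherited categories.
    return DeNovoStatus.UNKNOWN


#: Annotation columns collect_evidence requires.
MANDATORY_COLUMNS = ("gene", "cdna")


def collect_evidence(
    record: Mapping[str, object],
    fam: SegregationObservation | None = None,
) -> EvidenceSet:
    """Build an EvidenceSet from one annotation-table row.

    Expected columns: ``gene`` and ``cdna`` (mandatory); ``protein``,
    ``de_novo``, ``pmid``/``report_type``, ``popfreqmax``, ``conservation``,
    and damaging-prediction columns ``sift``/``polyphen``/``mutationtaster``
    (value ``D`` = damaging) are optional.  No absent slot is ever defaulted
    to a supportive value.
    """
    for col in MANDATORY_COLUMNS:
        if col not in record or record[col] in (None, "", "."):
            raise EvidenceError(f"missing mandatory annotation column: {col}")
    cdna = parse_cdna(str(record["cdna"]))
    protein = parse_protein(record.get("protein") and str(record["protein"]))
    nature = classify_consequence(cdna, protein)

    pmid = str(record.get("pmid", "") or "").strip()
    if record.get("report_type") in {e.value for e in PriorReport}:
        prior = PriorReport(str(record["report_type"]))
    elif pmid not in {"", ".", "NA"}:
        prior = PriorReport.FUNCTIONAL_STUDY
    else:
        prior = PriorReport.NONE

    insilico = sum(
        1
        for col in ("sift", "polyphen", "mutationtaster")
        if str(record.get(col, "")).strip().upper().startswith("D")
    )
    conservation = str(record.get("conservation", "")).strip().lower() in {
        "1",
        "true",
        "yes",
        "conserved",
    }
    return EvidenceSet(
        gene=str(record["gene"]),
        variant_nature=nature,
        cysteine=cysteine_involvement(protein),
        prior_report=prior,
        population_maf=parse_optional_float(record.get("popfreqmax")),  # type: ignore[arg-type]
        conservation_support=conservation,
        insilico_support=insilico,
        de_novo=_parse_de_novo(record.get("de_novo")),  # type: ignore[arg-type]
        segregation=fam,
    )


def classify(e: EvidenceSet) -> PathogenicityTier:
    """Deterministic rule-table classification (see module docstring)."""
    maf = e.population_maf
    if maf is not None and maf > 0.01:
        return PathogenicityTier.BENIGN

    if e.variant_nature in NULL_CLASSES:
        return (
            PathogenicityTier.PATHOGENIC
            if maf is None
            else PathogenicityTier.LIKELY_PATHOGENIC
        )

    tier = PathogenicityTier.VUS
    if e.variant_nature is MutationClass.MISSENSE and maf is None:
        fbn1_cys = e.gene == "FBN1" and e.cysteine is not CysteineInvolvement.NONE
        if fbn1_cys or e.prior_report is not PriorReport.NONE:
            tier = PathogenicityTier.LIKELY_PATHOGENIC
    if tier is PathogenicityTier.VUS and maf is not None:
        supported = (
            e.prior_report is not PriorReport.NONE
            or e.conservation_support
            or e.insilico_support >= 2
            or e.cysteine is not CysteineInvolvement.NONE
        )
        if not supported:
            tier = PathogenicityTier.LIKELY_BENIGN
    if tier is PathogenicityTier.VUS and e.de_novo is DeNovoStatus.CONFIRMED:
        tier = PathogenicityTier.LIKELY_PATHOGENIC
    return tier


def reclassify_with_segregation(
    prior: PathogenicityTier, s: SegregationObservation
) -> PathogenicityTier:
    """Adjust a called tier using family segregation.

    Demotion policy: any discordant observation caps a (likely) pathogenic
    call at VUS; the remaining weight of discordance then pushes a VUS to the
    benign side — one residual unaffected carrier argues likely benign, while
    an affected non-carrier (the variant simply fails to travel with disease)
    or two or more residual discordant observations argue benign.  Concordant
    carriage by two or more affected relatives, with no discordance, promotes
    a VUS to likely pathogenic.
    """
    if s.total_tested == 0:
        raise EvidenceError("segregation observation with zero relatives tested")

    d = s.discordant
    if d == 0:
        if prior is PathogenicityTier.VUS and s.affected_carrying >= 2:
            return PathogenicityTier.LIKELY_PATHOGENIC
        return prior

    tier = prior
    remaining_affected_noncarriers = s.affected_noncarriers
    if tier >= PathogenicityTier.LIKELY_PATHOGENIC:
        tier = PathogenicityTier.VUS
        # the first (strongest) discordant observation is spent on this step
        if remaining_affected_noncarriers > 0:
            remaining_affected_noncarriers -= 1
        d -= 1
    if tier is PathogenicityTier.VUS and d >= 1:
        tier = (
            PathogenicityTier.BENIGN
            if d >= 2 or remaining_affected_noncarriers > 0
            else PathogenicityTier.LIKELY_BENIGN
        )
    elif tier is PathogenicityTier.LIKELY_BENIGN and d >= 1:
        tier = PathogenicityTier.BENIGN
    return tier
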