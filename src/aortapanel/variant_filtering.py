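"""Post-calling triage filters for amplicon panel variant calls.

Three drop stages run in a fixed order — population frequency, recurrent
false-positive blacklist, indel confidence — followed by advisory flags
(amplicon-end proximity, off-target).  Flags never change a verdict's status;
they exist so a reviewer can see why a retained call is still suspect.

The indel-confidence rule ("DropIndel") keeps an insertion/deletion only when
all three predicates hold, with strict inequalities throughout:

* coverage depth > 20 reads,
* alt allele fraction > 10%,
* strand balance: alt reads on both strands > 3 and the two alt strand
  counts within a factor of 0.7 of each other (F/R > 0.7 and R/F > 0.7).

SNVs bypass the indel-confidence stage entirely.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .panel_model import PanelDefinition


class FilterInputError(ValueError):
    pass


class GenotypeState(str, Enum):
    CALLED = "called"
    NOCALL = "nocall"


@dataclass(frozen=True)
class VariantCall:
    """One biallelic called variant with its strand-resolved read support."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    depth: int
    alt_forward: int
    alt_reverse: int
    genotype: GenotypeState = GenotypeState.CALLED
    amplicon_id: str | None = None
    sample: str | None = None
    population_maf: float | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise FilterInputError(f"position {self.pos} < 1")
        if self.depth < 0:
            raise FilterInputError("negative depth")
        if min(self.alt_forward, self.alt_reverse) < 0:
            raise FilterInputError("negative strand read count")
        if self.alt_forward + self.alt_reverse > self.depth:
            raise FilterInputError(
                f"{self.key()}: alt reads {self.alt_forward}+{self.alt_reverse} "
                f"exceed depth {self.depth}"
            )

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != len(self.alt)

    @property
    def alt_reads(self) -> int:
        return self.alt_forward + self.alt_reverse

    @property
    def allele_fraction(self) -> float:
        return self.alt_reads / self.depth if self.depth > 0 else 0.0

    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class FilterConfig:
    """Triage thresholds; the defaults are the pipeline's operating point."""

    min_depth: int = 20  # reads, strict (depth must exceed this)
    min_allele_fraction: float = 0.10  # strict
    min_strand_reads: int = 3  # per strand, strict
    min_strand_ratio: float = 0.7  # both F/R and R/F must exceed this
    max_population_maf: float = 0.01  # drop if any database MAF exceeds 1%
    amplicon_end_margin: int = 5  # bases; advisory flag only

    def __post_init__(self) -> None:
        for name in (
            "min_depth",
            "min_allele_fraction",
            "min_strand_reads",
            "min_strand_ratio",
            "max_population_maf",
            "amplicon_end_margin",
        ):
            if getattr(self, name) <= 0:
                raise FilterInputError(f"{name} must be > 0")
        if self.min_strand_ratio > 1:
            raise FilterInputError("min_strand_ratio must be <= 1")


# ---------------------------------------------------------------------------
# Allele normalization (shared by blacklist lookups and the generator round trip)


def normalize_variant(
    chrom: str, pos: int, ref: str, alt: str, reference: Mapping[str, str]
) -> tuple[str, int, str, str]:
    """Left-align and trim an allele pair to its minimal VCF representation.

    ``reference`` maps contig name to its full sequence (0-based string).
    The same indel spelled at different anchors in a repeat tract normalizes
    to one canonical key.
    """
    seq = reference.get(chrom)
    ref, alt = ref.upper(), alt.upper()
    # trim identical trailing bases, extending left from the reference when
    # an allele would empty out (vt-style left alignment)
    while True:
        if len(ref) > 0 and len(alt) > 0 and ref[-1] == alt[-1] and (
            len(ref) > 1 or len(alt) > 1
        ):
            ref, alt = ref[:-1], alt[:-1]
            if not ref or not alt:
                if seq is None or pos <= 1:
                    raise FilterInputError(
                        f"cannot left-align {chrom}:{pos} without reference context"
                    )
                pos -= 1
                base = seq[pos - 1].upper()
                ref, alt = base + ref, base + alt
            continue
        break
    # trim identical leading bases (keep one anchor base for indels)
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return chrom, pos, ref, alt


@dataclass
class FalsePositiveList:
    """Recurrent artifact alleles accumulated from validated samples."""

    keys: frozenset[tuple[str, int, str, str]]
    provenance: str = ""

    @classmethod
    def from_tsv(
        cls, path: str | Path, reference: Mapping[str, str] | None = None
    ) -> "FalsePositiveList":
        keys: set[tuple[str, int, str, str]] = set()
        with open(path) as fh:
            header: list[str] | None = None
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if header is None:
                    header = parts
                    continue
                row = dict(zip(header, parts))
                key = (row["chrom"], int(row["pos"]), row["ref"], row["alt"])
                if reference is not None:
                    key = normalize_variant(*key, reference)
                keys.add(key)
        return cls(keys=frozenset(keys), provenance=str(path))

    def __contains__(self, key: tuple[str, int, str, str]) -> bool:
        return key in self.keys

    def __len__(self) -> int:
        return len(self.keys)


# ---------------------------------------------------------------------------
# Individual filter stages


def population_frequency_filter(maf: float | None, cfg: FilterConfig) -> bool:
    """True = keep.  A variant common in any population database (MAF above
    the 1% default) cannot cause a rare dominant aortopathy; absent
    annotation keeps the variant (novel variants are the interesting ones)."""
    if maf is None:
        return True
    if not 0 <= maf <= 1:
        raise FilterInputError(f"population MAF {maf} outside [0, 1]")
    return maf <= cfg.max_population_maf


def indel_confidence(v: VariantCall, cfg: FilterConfig) -> tuple[bool, list[str]]:
    """Evaluate the three DropIndel predicates; returns (passed, failed reasons)."""
    if v.depth <= 0:
        return False, ["no coverage"]
    reasons: list[str] = []
    if not v.depth > cfg.min_depth:
        reasons.append("depth")
    if not v.allele_fraction > cfg.min_allele_fraction:
        reasons.append("allele_fraction")
    f, r = v.alt_forward, v.alt_reverse
    if not (f > cfg.min_strand_reads and r > cfg.min_strand_reads):
        reasons.append("strand_reads")
    if f == 0 or r == 0:
        reasons.append("strand_ratio")
    elif not (f / r > cfg.min_strand_ratio and r / f > cfg.min_strand_ratio):
        reasons.append("strand_ratio")
    return (not reasons), reasons


def blacklist_filter(
    v: VariantCall,
    fpl: FalsePositiveList,
    reference: Mapping[str, str] | None = None,
) -> bool:
    """True when the (normalized) allele key is on the recurrent-artifact list."""
    key = v.key()
    if reference is not None:
        key = normalize_variant(*key, reference)
    return key in fpl


def amplicon_end_flag(
    v: VariantCall, panel: PanelDefinition, cfg: FilterConfig
) -> bool:
    """True when the call sits within the end margin of EVERY covering amplicon.

    Ends of amplicons accumulate primer-derived and mapping artifacts; but a
    position interior to any one covering amplicon has trustworthy support
    from that amplicon, so it is not flagged.
    """
    covering = panel.amplicons_covering(v.chrom, v.pos)
    if not covering:
        raise FilterInputError(f"{v.key()}: outside all amplicons")
    return all(
        a.distance_to_nearest_end(v.pos) < cfg.amplicon_end_margin for a in covering
    )


# ---------------------------------------------------------------------------
# Full triage


class TriageStatus(str, Enum):
    RETAINED = "retained"
    FREQUENCY_FILTERED = "frequency_filtered"
    BLACKLISTED = "blacklisted"
    DROP_INDEL = "DropIndel"


@dataclass
class TriageVerdict:
    call: VariantCall
    status: TriageStatus
    reasons: list[str] = field(default_factory=list)
    flags: set[str] = field(default_factory=set)

    @property
    def retained(self) -> bool:
        return self.status is TriageStatus.RETAINED


def triage(
    calls: Sequence[VariantCall],
    cfg: FilterConfig | None = None,
    fpl: FalsePositiveList | None = None,
    panel: PanelDefinition | None = None,
    reference: Mapping[str, str] | None = None,
) -> list[TriageVerdict]:
    """Apply the triage stages to every call, in input order.

    Stage order is fixed (frequency → blacklist → indel confidence) so that
    each call's recorded drop reason is reproducible; the retained set itself
    does not depend on the order.  Advisory flags are attached regardless of
    status when the panel's amplicon tiling is available.
    """
    cfg = cfg or FilterConfig()
    verdicts: list[TriageVerdict] = []
    for v in calls:
        status = TriageStatus.RETAINED
        reasons: list[str] = []
        try:
            if not population_frequency_filter(v.population_maf, cfg):
                status = TriageStatus.FREQUENCY_FILTERED
                reasons = [f"population_maf {v.population_maf} > {cfg.max_population_maf}"]
            elif fpl is not None and blacklist_filter(v, fpl, reference):
                status = TriageStatus.BLACKLISTED
                reasons = ["recurrent false-positive allele"]
            elif v.is_indel and v.genotype is GenotypeState.CALLED:
                ok, failed = indel_confidence(v, cfg)
                if not ok:
                    status = TriageStatus.DROP_INDEL
                    reasons = failed
        except FilterInputError as exc:
            raise FilterInputError(f"call {v.key()}: {exc}") from exc

        flags: set[str] = set()
        if panel is not None and panel.amplicons:
            if not panel.amplicons_covering(v.chrom, v.pos):
                flags.add("off_target")
            elif amplicon_end_flag(v, panel, cfg):
                flags.add("amplicon_end_proximal")
        verdicts.append(TriageVerdict(call=v, status=status, reasons=reasons, flags=flags))
    return verdicts


def split_multiallelic(
    chrom: str,
    pos: int,
    ref: str,
    alts: Sequence[str],
    depth: int,
    alt_forward: Sequence[int],
    alt_reverse: Sequence[int],
    **kwargs,
) -> list[VariantCall]:
    """Decompose a multi-allelic record into per-alt biallelic calls."""
    if not (len(alts) == len(alt_forward) == len(alt_reverse)):
        raise FilterInputError("per-allele strand counts must match alt count")
    return [
        VariantCall(
            chrom=chrom,
            pos=pos,
            ref=ref,
            alt=alt,
            depth=depth,
            alt_forward=alt_forward[i],
            alt_reverse=alt_reverse[i],
            **kwargs,
        )
        for i, alt in enumerate(alts)
    ]
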