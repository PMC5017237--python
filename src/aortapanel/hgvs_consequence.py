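"""Parse cDNA / protein HGVS strings and derive the mutation class.

The parser covers the HGVS subset that appears in clinical panel reports:
substitutions, deletions, insertions, duplications, deletion-insertions and
near-splice intronic changes (``c.6740-1G>A``).  It is deliberately not a full
HGVS grammar (no inversions, mosaicism or allele syntax).

Two modes exist.  Strict mode raises on anything unparseable.  Lenient mode
(the default for fixture loading) degrades gracefully: a malformed protein
string such as ``p.HisiSer656fs`` keeps its trailing-``fs`` semantics and is
tagged as an anomaly, so classification can fall back on the cDNA string.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum


class HgvsParseError(ValueError):
    """Raised in strict mode when an HGVS string cannot be parsed."""


class CdnaKind(str, Enum):
    SUBSTITUTION = "substitution"
    DELETION = "deletion"
    INSERTION = "insertion"
    DUPLICATION = "duplication"
    DELINS = "delins"
    INTRONIC = "intronic"
    OTHER = "other"


@dataclass(frozen=True)
class CdnaChange:
    """A parsed ``c.`` HGVS description."""

    raw: str
    kind: CdnaKind
    start: int | None = None
    end: int | None = None
    offset: int = 0  # signed intronic offset of the start position; 0 if exonic
    offset_end: int = 0
    ref: str | None = None  # substitution reference base(s)
    alt: str | None = None  # substitution alternate base(s)
    inserted: str | None = None  # ins/dup/delins inserted sequence
    deleted: str | None = None  # explicit deleted sequence if spelled out
    operation: CdnaKind | None = None  # underlying edit for intronic records

    @property
    def is_intronic(self) -> bool:
        return self.offset != 0 or self.offset_end != 0

    @property
    def span(self) -> int:
        """Number of reference bases named by the position range."""
        if self.start is None:
            return 0
        return (self.end or self.start) - self.start + 1

    def net_length_change(self) -> int | None:
        """Signed change in coding length; None when undecidable."""
        op = self.operation or self.kind
        if op is CdnaKind.SUBSTITUTION:
            return 0
        if op is CdnaKind.DELETION:
            return -(len(self.deleted) if self.deleted else self.span)
        if op is CdnaKind.INSERTION:
            return len(self.inserted) if self.inserted else None
        if op is CdnaKind.DUPLICATION:
            return len(self.inserted) if self.inserted else self.span
        if op is CdnaKind.DELINS:
            ins = len(self.inserted) if self.inserted else 0
            return ins - self.span
        return None

    def to_hgvs(self) -> str:
        """Re-serialize; byte-identical to the input for supported forms."""
        def pos(p: int | None, off: int) -> str:
            if p is None:
                return ""
            return f"{p}{off:+d}" if off else str(p)

        loc = pos(self.start, self.offset)
        if self.end is not None and (self.end, self.offset_end) != (self.start, self.offset):
            loc = f"{loc}_{pos(self.end, self.offset_end)}"
        op = self.operation or self.kind
        if op is CdnaKind.SUBSTITUTION:
            return f"c.{loc}{self.ref}>{self.alt}"
        if op is CdnaKind.DELETION:
            return f"c.{loc}del{self.deleted or ''}"
        if op is CdnaKind.INSERTION:
            return f"c.{loc}ins{self.inserted or ''}"
        if op is CdnaKind.DUPLICATION:
            return f"c.{loc}dup{self.inserted or ''}"
        if op is CdnaKind.DELINS:
            return f"c.{loc}delins{self.inserted or ''}"
        return self.raw


_POS = r"(\d+)([+-]\d+)?"
_CDNA_RE = re.compile(
    rf"^c\.{_POS}(?:_{_POS})?"
    r"(?:"
    r"([ACGTacgt]+)>([ACGTacgt]+)"  # substitution
    r"|delins([ACGTacgt]+)"  # deletion-insertion
    r"|del([ACGTacgt]*)"  # deletion
    r"|dup([ACGTacgt]*)"  # duplication
    r"|ins([ACGTacgt]+)"  # insertion
    r")$"
)


def parse_cdna(s: str, strict: bool = False) -> CdnaChange:
    """Parse a cDNA HGVS string.

    In lenient mode an unrecognized string yields ``kind=OTHER`` carrying the
    raw text; strict mode raises :class:`HgvsParseError`.
    """
    s = s.strip()
    if not s.startswith("c."):
        raise HgvsParseError(f"not a cDNA HGVS string: {s!r}")
    m = _CDNA_RE.match(s)
    if m is None:
        if strict:
            raise HgvsParseError(f"unparseable cDNA HGVS string: {s!r}")
        return CdnaChange(raw=s, kind=CdnaKind.OTHER)
    start, off1, end, off2, sub_ref, sub_alt, delins, dele, dup, ins = m.groups()
    start_i = int(start)
    end_i = int(end) if end is not None else start_i
    offset = int(off1) if off1 else 0
    offset_end = int(off2) if off2 else (offset if end is None else 0)

    if sub_ref is not None:
        op = CdnaKind.SUBSTITUTION
        ref, alt, inserted, deleted = sub_ref, sub_alt, None, None
    elif delins is not None:
        op, ref, alt, inserted, deleted = CdnaKind.DELINS, None, None, delins, None
    elif dele is not None:
        op, ref, alt, inserted, deleted = CdnaKind.DELETION, None, None, None, dele or None
    elif dup is not None:
        op, ref, alt, inserted, deleted = CdnaKind.DUPLICATION, None, None, dup or None, None
    else:
        op, ref, alt, inserted, deleted = CdnaKind.INSERTION, None, None, ins, None

    intronic = offset != 0 or offset_end != 0
    return CdnaChange(
        raw=s,
        kind=CdnaKind.INTRONIC if intronic else op,
        start=start_i,
        end=end_i,
        offset=offset,
        offset_end=offset_end,
        ref=ref,
        alt=alt,
        inserted=inserted,
        deleted=deleted,
        operation=op if intronic else None,
    )


# ---------------------------------------------------------------------------
# Protein HGVS

_AA3 = (
    "Ala|Arg|Asn|Asp|Cys|Gln|Glu|Gly|His|Ile|Leu|Lys|Met|Phe|Pro|Ser|Thr|Trp|Tyr|Val|Ter"
)
_PROT_POINT_RE = re.compile(rf"^p\.({_AA3})(\d+)(?:({_AA3})|(fs.*))$")
_PROT_RANGE_RE = re.compile(
    rf"^p\.(?:({_AA3}))?(\d+)_(?:({_AA3}))?(\d+)(del|dup|ins[A-Za-z]*)$"
)


@dataclass(frozen=True)
class ProteinChange:
    """A parsed ``p.`` HGVS description (lenient where the source text is sloppy)."""

    raw: str
    ref: str | None = None  # three-letter reference residue
    position: int | None = None
    end_position: int | None = None
    alt: str | None = None  # three-letter alternate residue, or None
    frameshift: bool = False
    termination: bool = False  # alt is a stop (Ter)
    startloss: bool = False  # initiator Met altered
    range_op: str | None = None  # del/dup/ins for multi-residue events
    anomaly: bool = False  # lenient parse of a malformed string

    @property
    def is_substitution(self) -> bool:
        return (
            self.ref is not None
            and self.alt is not None
            and not self.frameshift
            and self.range_op is None
        )


def parse_protein(s: str | None, strict: bool = False) -> ProteinChange | None:
    """Parse a protein HGVS string; empty/absent input returns None.

    Flags follow the usual reading: trailing ``fs`` marks a frameshift,
    ``Ter`` as the alternate residue marks a stop gain, and any edit of the
    initiator ``Met1`` is a start loss.
    """
    if s is None:
        return None
    s = s.strip()
    if s in {"", ".", "NA", "nan", "None"}:
        return None
    if not s.startswith("p."):
        raise HgvsParseError(f"not a protein HGVS string: {s!r}")

    m = _PROT_POINT_RE.match(s)
    if m:
        ref, pos, alt, fs = m.groups()
        position = int(pos)
        frameshift = fs is not None
        termination = alt == "Ter"
        startloss = position == 1 and ref == "Met" and (frameshift or alt != "Met")
        return ProteinChange(
            raw=s,
            ref=ref,
            position=position,
            alt=None if frameshift else alt,
            frameshift=frameshift,
            termination=termination,
            startloss=startloss,
        )

    m = _PROT_RANGE_RE.match(s)
    if m:
        ref, pos, _alt_res, end_pos, op = m.groups()
        return ProteinChange(
            raw=s,
            ref=ref,
            position=int(pos),
            end_position=int(end_pos),
            range_op="ins" if op.startswith("ins") else op,
        )

    if strict:
        raise HgvsParseError(f"unparseable protein HGVS string: {s!r}")
    # Lenient fallback: keep whatever semantics are still legible.
    return ProteinChange(
        raw=s,
        frameshift=s.endswith("fs") or "fs" in s[-4:],
        termination=s.endswith("Ter"),
        anomaly=True,
    )


# ---------------------------------------------------------------------------
# Mutation class

class MutationClass(str, Enum):
    """Consequence category used for classification and genotype-phenotype grouping."""

    MISSENSE = "missense"
    STOPGAIN = "stopgain"
    FRAMESHIFT_INSERTION = "frameshift_insertion"
    FRAMESHIFT_DELETION = "frameshift_deletion"
    NONFRAMESHIFT_INDEL = "nonframeshift_indel"
    SPLICING = "splicing"
    STARTLOSS = "startloss"
    SYNONYMOUS = "synonymous"
    OTHER = "other"

    @property
    def truncating(self) -> bool:
        return self in {
            MutationClass.STOPGAIN,
            MutationClass.FRAMESHIFT_INSERTION,
            MutationClass.FRAMESHIFT_DELETION,
        }

    @property
    def truncating_or_splicing(self) -> bool:
        return self.truncating or self is MutationClass.SPLICING


#: Classes treated as protein-null for pathogenicity purposes.
NULL_CLASSES = {
    MutationClass.STOPGAIN,
    MutationClass.FRAMESHIFT_INSERTION,
    MutationClass.FRAMESHIFT_DELETION,
    MutationClass.SPLICING,
    MutationClass.STARTLOSS,
}


class ConsequenceError(ValueError):
    """Strict-mode error for contradictory cDNA/protein inputs."""


def _frameshift_direction(c: CdnaChange | None) -> MutationClass:
    if c is not None:
        net = c.net_length_change()
        op = c.operation or c.kind
        if op in {CdnaKind.INSERTION, CdnaKind.DUPLICATION}:
            return MutationClass.FRAMESHIFT_INSERTION
        if op is CdnaKind.DELETION:
            return MutationClass.FRAMESHIFT_DELETION
        if net is not None and net != 0:
            return (
                MutationClass.FRAMESHIFT_INSERTION
                if net > 0
                else MutationClass.FRAMESHIFT_DELETION
            )
    return MutationClass.OTHER


def classify_consequence(
    c: CdnaChange | None, p: ProteinChange | None, strict: bool = False
) -> MutationClass:
    """Assign the mutation class from the parsed cDNA and protein changes.

    Splicing is defined positionally: an intronic offset of magnitude 1 or 2
    (the canonical donor/acceptor dinucleotides).  Deeper intronic changes are
    ``other``.  When the protein string describes a clean single-residue
    substitution (even for an MNV spelled as delins), the class is missense;
    duplications group with insertions; delins events resolve by the sign of
    the net length change.
    """
    if c is None and p is None:
        raise ValueError("at least one of cDNA/protein change required")

    if c is not None and c.is_intronic:
        offsets = [o for o in (c.offset, c.offset_end) if o != 0]
        if any(abs(o) in (1, 2) for o in offsets):
            return MutationClass.SPLICING
        return MutationClass.OTHER

    if p is not None and not p.anomaly:
        if p.frameshift:
            return _frameshift_direction(c)
        if p.startloss:
            return MutationClass.STARTLOSS
        if p.termination:
            return MutationClass.STOPGAIN
        if p.is_substitution:
            return (
                MutationClass.SYNONYMOUS if p.ref == p.alt else MutationClass.MISSENSE
            )
        if p.range_op is not None:
            net = c.net_length_change() if c is not None else None
            if net is not None and net % 3 != 0:
                return _frameshift_direction(c)
            return MutationClass.NONFRAMESHIFT_INDEL

    if p is not None and p.anomaly and p.frameshift:
        return _frameshift_direction(c)

    # No usable protein change: fall back to the cDNA edit.
    if c is not None:
        op = c.operation or c.kind
        if op in {
            CdnaKind.DELETION,
            CdnaKind.INSERTION,
            CdnaKind.DUPLICATION,
            CdnaKind.DELINS,
        }:
            net = c.net_length_change()
            if net is not None and net % 3 != 0:
                return _frameshift_direction(c)
            return MutationClass.NONFRAMESHIFT_INDEL
        if op is CdnaKind.SUBSTITUTION:
            if strict:
                raise ConsequenceError(
                    f"exonic substitution {c.raw} lacks a protein consequence"
                )
            return MutationClass.OTHER
    if strict:
        raise ConsequenceError("inputs insufficient to classify")
    return MutationClass.OTHER


# ---------------------------------------------------------------------------
# Cysteine involvement

class CysteineInvolvement(str, Enum):
    DESTROYS_CYS = "destroys_cys"
    CREATES_CYS = "creates_cys"
    NONE = "none"


def cysteine_involvement(p: ProteinChange | None) -> CysteineInvolvement:
    """Whether a single-residue substitution removes or introduces a cysteine.

    In fibrillin-1 the cysteines of the EGF-like domains form disulfide
    bridges, so either direction of change is strong pathogenicity evidence.
    Non-missense or absent protein changes return NONE.
    """
    if p is None or not p.is_substitution:
        return CysteineInvolvement.NONE
    if p.ref == "Cys" and p.alt != "Cys":
        return CysteineInvolvement.DESTROYS_CYS
    if p.alt == "Cys" and p.ref != "Cys":
        return CysteineInvolvement.CREATES_CYS
    return CysteineInvolvement.NONE
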