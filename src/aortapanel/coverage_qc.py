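"""Coverage statistics, low-coverage exon listing and hotspot NoCall alerts.

The QC layer watches for false *negatives*: exons whose read depth dips below
the callable threshold are queued for confirmatory Sanger sequencing, and any
FBN1 cysteine-codon base that is NoCall (or silently uncovered) raises an
alert naming the exon to confirm.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from ._utils import round_half_up
from .panel_model import HotspotSet, PanelDefinition, TranscriptModel
from .variant_filtering import GenotypeState, VariantCall

#: Depth at and above which a base is considered reliably callable.
DEFAULT_MIN_DEPTH = 20


class CoverageError(ValueError):
    pass


@dataclass
class CoverageTrack:
    """Per-base depth as (chrom, start, end, depth) runs, BED-graph style (0-based half-open)."""

    intervals: list[tuple[str, int, int, int]]

    def __post_init__(self) -> None:
        for chrom, start, end, depth in self.intervals:
            if depth < 0:
                raise CoverageError(f"negative depth at {chrom}:{start}-{end}")
            if not 0 <= start < end:
                raise CoverageError(f"bad interval {chrom}:{start}-{end}")

    @classmethod
    def from_bedgraph(cls, path: str | Path) -> "CoverageTrack":
        intervals = []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track")):
                    continue
                chrom, start, end, depth = line.split("\t")[:4]
                intervals.append((chrom, int(start), int(end), int(depth)))
        return cls(intervals=intervals)

    def to_bedgraph(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom, start, end, depth in self.intervals:
                fh.write(f"{chrom}\t{start}\t{end}\t{depth}\n")

    def depth_at(self, chrom: str, pos: int) -> int:
        """Depth at a 1-based position; uncovered positions are depth 0."""
        for c, s, e, d in self.intervals:
            if c == chrom and s < pos <= e:
                return d
        return 0

    def depths_over(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Depth vector over a 0-based half-open interval (0 where untracked)."""
        out = np.zeros(end - start, dtype=np.int64)
        for c, s, e, d in self.intervals:
            if c != chrom:
                continue
            lo, hi = max(s, start), min(e, end)
            if lo < hi:
                out[lo - start : hi - start] = d
        return out


def coverage_summary(
    track: CoverageTrack,
    panel: PanelDefinition,
    min_depth: int = DEFAULT_MIN_DEPTH,
) -> tuple[float, float]:
    """Base-weighted mean depth and the fraction of panel bases at/above ``min_depth``.

    The denominator is the merged amplicon footprint; bases the track does not
    mention count as depth 0.
    """
    footprint = panel.footprint()
    if not footprint:
        raise CoverageError("panel has no amplicon footprint")
    total_bases = 0
    total_depth = 0
    covered = 0
    for chrom, intervals in footprint.items():
        for start, end in intervals:
            depths = track.depths_over(chrom, start, end)
            total_bases += depths.size
            total_depth += int(depths.sum())
            covered += int((depths >= min_depth).sum())
    return total_depth / total_bases, covered / total_bases


@dataclass(frozen=True)
class LowCoverageExon:
    gene: str
    exon_label: str
    min_depth: int


def low_coverage_exons(
    track: CoverageTrack,
    tm: TranscriptModel,
    min_depth: int = DEFAULT_MIN_DEPTH,
) -> list[LowCoverageExon]:
    """Exons with ANY base below ``min_depth`` (these go to Sanger confirmation)."""
    flagged: list[LowCoverageExon] = []
    for number, (start, end) in enumerate(tm.exons_transcript_order(), start=1):
        depths = track.depths_over(tm.chrom, start, end)
        lowest = int(depths.min()) if depths.size else 0
        if lowest < min_depth:
            flagged.append(
                LowCoverageExon(gene=tm.gene, exon_label=f"exon{number}", min_depth=lowest)
            )
    return flagged


@dataclass(frozen=True)
class HotspotAlert:
    position: int  # 1-based genomic
    exon_label: str
    reason: str  # "NoCall" or "no call record, depth < threshold"


def hotspot_nocall_alerts(
    calls: Sequence[VariantCall],
    track: CoverageTrack,
    hs: HotspotSet,
    tm: TranscriptModel,
    min_depth: int = DEFAULT_MIN_DEPTH,
) -> list[HotspotAlert]:
    """One alert per hotspot base that is NoCall or silently under-covered.

    A position alerts when the caller emitted a no-genotype record there, or
    when no record exists at all and the depth is below ``min_depth`` (the
    caller could not have seen a variant).  A reference-called or
    variant-called hotspot at adequate depth is silent.
    """
    nocall_positions = {
        v.pos for v in calls if v.genotype is GenotypeState.NOCALL and v.chrom == tm.chrom
    }
    recorded_positions = {v.pos for v in calls if v.chrom == tm.chrom}
    alerts: list[HotspotAlert] = []
    for pos in sorted(hs.positions):
        exon = tm.exon_number_of(pos)
        label = f"exon{exon}" if exon is not None else "intron"
        if pos in nocall_positions:
            alerts.append(HotspotAlert(pos, label, "NoCall"))
        elif pos not in recorded_positions and track.depth_at(tm.chrom, pos) < min_depth:
            alerts.append(HotspotAlert(pos, label, "no call record, depth < threshold"))
    assert all(a.position in hs for a in alerts)
    return alerts


@dataclass
class QcReport:
    """Panel-level QC summary plus the false-negative surveillance lists."""

    mean_depth: float
    fraction_callable: float
    low_coverage: list[LowCoverageExon] = field(default_factory=list)
    hotspot_alerts: list[HotspotAlert] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0 <= self.fraction_callable <= 1:
            raise CoverageError("fraction_callable outside [0, 1]")

    @property
    def confirmation_exons(self) -> list[str]:
        """Distinct exons to send for confirmatory sequencing (set semantics)."""
        labels = {e.exon_label for e in self.low_coverage}
        labels |= {a.exon_label for a in self.hotspot_alerts if a.exon_label != "intron"}
        return sorted(labels, key=lambda s: int(s.replace("exon", "") or 0))

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "mean_depth": round_half_up(self.mean_depth, 1),
            "fraction_callable": round_half_up(self.fraction_callable, 3),
            "low_coverage_exons": [asdict(e) for e in self.low_coverage],
            "hotspot_alerts": [asdict(a) for a in self.hotspot_alerts],
            "confirmation_exons": self.confirmation_exons,
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text


def qc_report(
    track: CoverageTrack,
    panel: PanelDefinition,
    calls: Sequence[VariantCall],
    tm: TranscriptModel,
    hs: HotspotSet,
    min_depth: int = DEFAULT_MIN_DEPTH,
) -> QcReport:
    """Assemble the full QC report for one sample."""
    mean_depth, fraction = coverage_summary(track, panel, min_depth)
    return QcReport(
        mean_depth=mean_depth,
        fraction_callable=fraction,
        low_coverage=low_coverage_exons(track, tm, min_depth),
        hotspot_alerts=hotspot_nocall_alerts(calls, track, hs, tm, min_depth),
    )
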