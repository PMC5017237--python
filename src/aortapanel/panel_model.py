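"""Panel definition, amplicon intervals, transcript models and the FBN1 cysteine hotspot set.

Coordinate conventions
----------------------
Variant and hotspot positions are 1-based inclusive (VCF convention).  Interval
files (amplicon BED, genePred exon bounds) are 0-based half-open (BED
convention).  The conversion happens only inside this I/O layer; everything
downstream works with 1-based positions and opaque interval objects.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio.Seq import Seq


class PanelValidationError(ValueError):
    """The file parsed, but its content violates a panel invariant."""


class PanelParseError(ValueError):
    """A line could not be parsed; the message carries the line number."""


@dataclass(frozen=True)
class PanelGene:
    """One gene of the aortopathy panel with its design-level statistics."""

    symbol: str
    locus: str
    disease: str
    exon_count: int
    amplicon_count: int
    design_coverage: float

    def __post_init__(self) -> None:
        if self.exon_count <= 0:
            raise PanelValidationError(f"{self.symbol}: exon_count must be > 0")
        if self.amplicon_count <= 0:
            raise PanelValidationError(f"{self.symbol}: amplicon_count must be > 0")
        if not 0 < self.design_coverage <= 1:
            raise PanelValidationError(
                f"{self.symbol}: design_coverage {self.design_coverage} outside (0, 1]"
            )


@dataclass(frozen=True)
class Amplicon:
    """A PCR amplicon interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    gene: str
    amplicon_id: str

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise PanelValidationError(
                f"amplicon {self.amplicon_id}: bad interval [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, chrom: str, pos: int) -> bool:
        """Membership of a 1-based position."""
        return chrom == self.chrom and self.start < pos <= self.end

    def distance_to_nearest_end(self, pos: int) -> int:
        """Distance (bases) from a 1-based position to the closer amplicon boundary."""
        return min(pos - (self.start + 1), self.end - pos)


@dataclass
class PanelDefinition:
    """The gene list plus (optionally) the amplicon tiling of the panel."""

    genes: list[PanelGene]
    amplicons: list[Amplicon] = field(default_factory=list)

    def __post_init__(self) -> None:
        symbols = [g.symbol for g in self.genes]
        if len(symbols) != len(set(symbols)):
            dup = sorted({s for s in symbols if symbols.count(s) > 1})
            raise PanelValidationError(f"duplicate gene symbol(s): {', '.join(dup)}")
        known = set(symbols)
        for amp in self.amplicons:
            if amp.gene not in known:
                raise PanelValidationError(
                    f"amplicon {amp.amplicon_id} maps to unknown gene {amp.gene}"
                )

    @property
    def gene_count(self) -> int:
        return len(self.genes)

    @property
    def gene_symbols(self) -> set[str]:
        return {g.symbol for g in self.genes}

    def gene(self, symbol: str) -> PanelGene:
        for g in self.genes:
            if g.symbol == symbol:
                return g
        raise KeyError(symbol)

    def amplicons_covering(self, chrom: str, pos: int) -> list[Amplicon]:
        """All amplicons containing the 1-based position."""
        return [a for a in self.amplicons if a.contains(chrom, pos)]

    def footprint(self) -> dict[str, list[tuple[int, int]]]:
        """Merged amplicon intervals per chromosome, 0-based half-open."""
        out: dict[str, list[tuple[int, int]]] = {}
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for a in self.amplicons:
            by_chrom.setdefault(a.chrom, []).append((a.start, a.end))
        for chrom, ivals in by_chrom.items():
            merged: list[tuple[int, int]] = []
            for s, e in sorted(ivals):
                if merged and s <= merged[-1][1]:
                    merged[-1] = (merged[-1][0], max(merged[-1][1], e))
                else:
                    merged.append((s, e))
            out[chrom] = merged
        return out


def load_panel_definition(
    panel_path: str | Path, amplicons_path: str | Path | None = None
) -> PanelDefinition:
    """Load the panel gene table (TSV) and, if given, the amplicon BED.

    The panel TSV has a header row: symbol, locus, protein (ignored for the
    model), disease, exons, amplicons, coverage.  Raises
    :class:`PanelValidationError` on duplicate symbols or an empty file and
    :class:`PanelParseError` (with line number) on malformed rows.
    """
    genes: list[PanelGene] = []
    with open(panel_path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise PanelValidationError(f"{panel_path}: empty panel file")
        required = {"symbol", "locus", "disease", "exons", "amplicons", "coverage"}
        missing = required - set(reader.fieldnames)
        if missing:
            raise PanelValidationError(
                f"{panel_path}: missing column(s) {', '.join(sorted(missing))}"
            )
        for lineno, row in enumerate(reader, start=2):
            try:
                genes.append(
                    PanelGene(
                        symbol=row["symbol"].strip(),
                        locus=row["locus"].strip(),
                        disease=row["disease"].strip(),
                        exon_count=int(row["exons"]),
                        amplicon_count=int(row["amplicons"]),
                        design_coverage=float(row["coverage"]),
                    )
                )
            except (KeyError, ValueError, TypeError) as exc:
                if isinstance(exc, PanelValidationError):
                    raise
                raise PanelParseError(f"{panel_path}:{lineno}: {exc}") from exc
    if not genes:
        raise PanelValidationError(f"{panel_path}: no gene rows")
    amplicons = list(load_amplicons(amplicons_path)) if amplicons_path else []
    return PanelDefinition(genes=genes, amplicons=amplicons)


def load_amplicons(path: str | Path) -> Iterable[Amplicon]:
    """Read an amplicon BED (chrom, start, end, gene, amplicon_id)."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 5:
                raise PanelParseError(f"{path}:{lineno}: expected 5 columns, got {len(parts)}")
            try:
                yield Amplicon(parts[0], int(parts[1]), int(parts[2]), parts[3], parts[4])
            except ValueError as exc:
                raise PanelParseError(f"{path}:{lineno}: {exc}") from exc


# ---------------------------------------------------------------------------
# Transcript models


class TranscriptValidationError(ValueError):
    pass


@dataclass
class TranscriptModel:
    """A single (canonical) transcript: exon structure plus its CDS sequence.

    ``exons`` are 0-based half-open genomic intervals in ascending genomic
    order; ``cds_start``/``cds_end`` bound the coding region on the genome the
    same way; ``cds_sequence`` is the spliced coding sequence in translation
    order (reverse-complemented already for minus-strand genes).
    """

    gene: str
    accession: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_start: int
    cds_end: int
    cds_sequence: str

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise TranscriptValidationError(f"{self.accession}: bad strand {self.strand!r}")
        prev_end = -1
        for s, e in self.exons:
            if not 0 <= s < e:
                raise TranscriptValidationError(f"{self.accession}: bad exon [{s}, {e})")
            if s < prev_end:
                raise TranscriptValidationError(
                    f"{self.accession}: exons overlap or are unordered"
                )
            prev_end = e
        if len(self.cds_sequence) % 3 != 0:
            raise TranscriptValidationError(
                f"{self.accession}: CDS length {len(self.cds_sequence)} not divisible by 3"
            )
        n_genomic = len(self._cds_positions_ascending())
        if n_genomic != len(self.cds_sequence):
            raise TranscriptValidationError(
                f"{self.accession}: CDS sequence length {len(self.cds_sequence)} "
                f"does not match exonic CDS extent {n_genomic}"
            )
        aa = str(Seq(self.cds_sequence).translate())
        if "*" in aa[:-1]:
            raise TranscriptValidationError(f"{self.accession}: internal stop codon in CDS")

    # -- coordinate plumbing -------------------------------------------------

    def _cds_positions_ascending(self) -> list[int]:
        pos: list[int] = []
        for s, e in self.exons:
            lo, hi = max(s, self.cds_start), min(e, self.cds_end)
            if lo < hi:
                pos.extend(range(lo + 1, hi + 1))  # 1-based inclusive
        return pos

    def cds_genomic_positions(self) -> list[int]:
        """1-based genomic positions of the CDS bases in translation order."""
        pos = self._cds_positions_ascending()
        return pos[::-1] if self.strand == "-" else pos

    @property
    def exon_count(self) -> int:
        return len(self.exons)

    def exons_transcript_order(self) -> list[tuple[int, int]]:
        """Exons in transcript (5'→3') order; coordinates stay genomic."""
        return list(self.exons[::-1] if self.strand == "-" else self.exons)

    def exon_number_of(self, pos: int) -> int | None:
        """1-based exon number (transcript order) containing a 1-based position."""
        for i, (s, e) in enumerate(self.exons_transcript_order(), start=1):
            if s < pos <= e:
                return i
        return None

    def codons(self) -> list[tuple[str, tuple[int, int, int]]]:
        """(codon, genomic positions of its three bases) in translation order."""
        gpos = self.cds_genomic_positions()
        seq = self.cds_sequence.upper()
        return [
            (seq[i : i + 3], (gpos[i], gpos[i + 1], gpos[i + 2]))
            for i in range(0, len(seq), 3)
        ]

    def protein(self) -> str:
        return str(Seq(self.cds_sequence).translate())


def load_transcript_models(
    genepred_path: str | Path, cds_fasta_path: str | Path
) -> dict[str, TranscriptModel]:
    """Read a genePred-extended TSV plus a FASTA of CDS sequences (keyed by accession).

    genePred columns used: name, chrom, strand, txStart, txEnd, cdsStart,
    cdsEnd, exonCount, exonStarts, exonEnds, score, name2 (gene symbol).
    """
    from Bio import SeqIO

    cds_seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(cds_fasta_path), "fasta")}
    models: dict[str, TranscriptModel] = {}
    with open(genepred_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 12:
                raise PanelParseError(
                    f"{genepred_path}:{lineno}: expected >=12 genePred columns, got {len(parts)}"
                )
            name, chrom, strand = parts[0], parts[1], parts[2]
            cds_start, cds_end = int(parts[5]), int(parts[6])
            n_exon = int(parts[7])
            starts = [int(x) for x in parts[8].rstrip(",").split(",")]
            ends = [int(x) for x in parts[9].rstrip(",").split(",")]
            gene = parts[11]
            if len(starts) != n_exon or len(ends) != n_exon:
                raise PanelParseError(
                    f"{genepred_path}:{lineno}: exonCount disagrees with exon lists"
                )
            if name not in cds_seqs:
                raise TranscriptValidationError(f"{name}: no CDS sequence in FASTA")
            models[gene] = TranscriptModel(
                gene=gene,
                accession=name,
                chrom=chrom,
                strand=strand,
                exons=tuple(zip(starts, ends)),
                cds_start=cds_start,
                cds_end=cds_end,
                cds_sequence=cds_seqs[name],
            )
    return models


def load_transcript_model(
    genepred_path: str | Path, gene: str, cds_fasta_path: str | Path
) -> TranscriptModel:
    """Load the transcript model for one panel gene."""
    models = load_transcript_models(genepred_path, cds_fasta_path)
    if gene not in models:
        raise KeyError(f"gene {gene} not present in {genepred_path}")
    return models[gene]


# ---------------------------------------------------------------------------
# Cysteine hotspots

#: Codons encoding cysteine.
CYS_CODONS = {"TGT", "TGC"}


@dataclass(frozen=True)
class HotspotSet:
    """Genomic positions (1-based) monitored for false negatives.

    For FBN1 this is every base of every cysteine codon: disulfide-bonding
    cysteines in the fibrillin-1 EGF-like domains are structurally essential,
    so a missed call at any of these bases is clinically unacceptable.
    """

    gene: str
    positions: frozenset[int]
    provenance: str = "all cysteine codon bases of the canonical transcript"

    def __contains__(self, pos: int) -> bool:
        return pos in self.positions

    def __len__(self) -> int:
        return len(self.positions)


def cysteine_hotspots(tm: TranscriptModel) -> HotspotSet:
    """Genomic positions of all three bases of every Cys (TGT/TGC) codon."""
    positions: set[int] = set()
    for codon, gpos in tm.codons():
        if codon in CYS_CODONS:
            positions.update(gpos)
    return HotspotSet(gene=tm.gene, positions=frozenset(positions))
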