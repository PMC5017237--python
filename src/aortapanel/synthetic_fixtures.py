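"""Packaged report-table fixtures and the truth-labelled synthetic callset generator.

Fixtures
--------
Machine-readable transcriptions of the published panel design, cohort
cross-tab, mutation list, FBN1 genotype-phenotype table and reclassification
table ship under ``aortapanel/data``.  :func:`load_fixtures` validates row
counts, internal sums and file checksums at load time, so a silently edited
fixture fails loudly.  The reclassification fixture carries *reconstructed*
segregation observation counts (its header says so): the printed table gives
outcomes, not pedigree counts, so counts consistent with each outcome and
case narrative were encoded once and are flagged as reconstructions.

Synthetic callsets
------------------
The generator builds a single-contig coordinate frame ("panel1") with a
non-overlapping amplicon tiling and an FBN1-like multi-exon transcript whose
CDS contains cysteine codons.  Each emitted call carries a truth label:

* ``true_variant`` — indels satisfy all three confidence predicates;
* ``end_of_amplicon_artifact`` — within the end margin of its amplicon;
* ``strand_bias_artifact`` — violates the strand-reads or strand-ratio
  predicate (choice per call, recorded in the truth table);
* ``blacklisted_recurrent`` — allele present on the generated blacklist;
* ``hotspot_nocall_site`` — a NoCall record at a cysteine hotspot base.

Everything is a pure function of (params, seed).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._utils import parse_optional_float, round_half_up
from .acmg_classifier import PathogenicityTier, SegregationObservation
from .cohort_report import (
    AorticEvent,
    ClassifiedVariant,
    Diagnosis,
    GP_CLASSES,
    Proband,
    ROLLUP_ROW,
    weighted_mean_age,
)
from .coverage_qc import CoverageTrack
from .hgvs_consequence import MutationClass
from .panel_model import (
    Amplicon,
    HotspotSet,
    PanelDefinition,
    TranscriptModel,
    cysteine_hotspots,
    load_panel_definition,
)
from .variant_filtering import (
    FalsePositiveList,
    GenotypeState,
    TriageStatus,
    TriageVerdict,
    VariantCall,
)

DATA_DIR = Path(__file__).parent / "data"


class FixtureError(ValueError):
    """A fixture failed checksum or internal-consistency validation."""


# ---------------------------------------------------------------------------
# Fixture bundle


@dataclass
class FixtureBundle:
    panel: PanelDefinition
    cohort_table: pd.DataFrame  # diagnosis x (cases, pathogenic, vus, negative)
    mutations: pd.DataFrame  # the published (likely) pathogenic / VUS list
    genotype_phenotype: pd.DataFrame  # tidy class x event cells
    reclassification: pd.DataFrame  # 18 reclassified variants + reconstructed observations
    inconsistent_cells: list[str] = field(default_factory=list)

    def segregation_observations(self) -> list[tuple[PathogenicityTier, SegregationObservation, PathogenicityTier]]:
        """(called tier, observation, printed reclassified tier) per fixture row."""
        out = []
        for _, row in self.reclassification.iterrows():
            out.append(
                (
                    PathogenicityTier.from_label(row["called"]),
                    SegregationObservation(
                        affected_tested=int(row["aff_tested"]),
                        affected_carrying=int(row["aff_carrying"]),
                        unaffected_tested=int(row["unaff_tested"]),
                        unaffected_carrying=int(row["unaff_carrying"]),
                    ),
                    PathogenicityTier.from_label(row["reclassified"]),
                )
            )
        return out


def _read_tsv(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)


def _verify_checksums(data_dir: Path) -> None:
    manifest_path = data_dir / "manifest.json"
    if not manifest_path.exists():
        return
    manifest = json.loads(manifest_path.read_text())
    for name, expected in manifest.items():
        p = data_dir / name
        if not p.exists():
            raise FixtureError(f"fixture file missing: {name}")
        actual = hashlib.sha256(p.read_bytes()).hexdigest()
        if actual != expected:
            raise FixtureError(f"fixture checksum mismatch: {name}")


def load_fixtures(data_dir: str | Path | None = None, verify_checksums: bool = True) -> FixtureBundle:
    """Load and validate the packaged table fixtures.

    Raises :class:`FixtureError` naming the offending file/cell on any
    checksum failure, wrong row count, or internal-sum violation.
    """
    data_dir = Path(data_dir) if data_dir is not None else DATA_DIR
    if verify_checksums:
        _verify_checksums(data_dir)

    panel = load_panel_definition(data_dir / "panel_genes.tsv")
    if panel.gene_count != 15:
        raise FixtureError(f"panel_genes.tsv: expected 15 genes, found {panel.gene_count}")

    cohort = _read_tsv(data_dir / "cohort_results.tsv")
    for col in ("cases", "pathogenic", "vus", "negative"):
        cohort[col] = cohort[col].astype(int)
    if len(cohort) != 5:
        raise FixtureError("cohort_results.tsv: expected 4 diagnosis rows + Total")
    body = cohort[cohort["diagnosis"] != "Total"]
    total = cohort[cohort["diagnosis"] == "Total"].iloc[0]
    for _, row in cohort.iterrows():
        if row["cases"] != row["pathogenic"] + row["vus"] + row["negative"]:
            raise FixtureError(
                f"cohort_results.tsv: row '{row['diagnosis']}' cases {row['cases']} "
                f"!= sum of result columns"
            )
    for col in ("cases", "pathogenic", "vus", "negative"):
        if int(body[col].sum()) != int(total[col]):
            raise FixtureError(
                f"cohort_results.tsv: Total cell '{col}' {total[col]} != column sum {body[col].sum()}"
            )

    mutations = _read_tsv(data_dir / "mutations.tsv")
    if len(mutations) != 87:
        raise FixtureError(f"mutations.tsv: expected 87 rows, found {len(mutations)}")

    gp = _read_tsv(data_dir / "fbn1_genotype_phenotype.tsv")
    gp["count"] = gp["count"].astype(int)
    gp["mean_age"] = gp["mean_age"].map(parse_optional_float)
    if len(gp) != 24:
        raise FixtureError(f"fbn1_genotype_phenotype.tsv: expected 24 cells, found {len(gp)}")
    inconsistent: list[str] = []
    sub_classes = [mc.value for mc in GP_CLASSES]
    for event, cells in gp.groupby("event"):
        cells = cells.set_index("mutation_class")
        rollup = cells.loc[ROLLUP_ROW]
        sub = cells.loc[sub_classes]
        if int(rollup["count"]) != int(sub["count"].sum()):
            raise FixtureError(
                f"fbn1_genotype_phenotype.tsv: rollup count for event '{event}' "
                f"{rollup['count']} != {int(sub['count'].sum())}"
            )
        pairs = [
            (int(r["count"]), float(r["mean_age"]))
            for _, r in sub.iterrows()
            if r["count"] > 0 and r["mean_age"] is not None
        ]
        computed = weighted_mean_age(pairs)
        printed = rollup["mean_age"]
        cell_name = f"{ROLLUP_ROW}/{event}"
        if printed is not None and computed is not None and abs(printed - computed) > 0.05:
            if rollup["flag"] != "age_inconsistent":
                raise FixtureError(
                    f"fbn1_genotype_phenotype.tsv: rollup age for '{cell_name}' is "
                    f"{printed} but sub-rows give {computed} and the cell is not flagged"
                )
            inconsistent.append(cell_name)

    reclass = _read_tsv(data_dir / "reclassified_variants.tsv")
    if len(reclass) != 18:
        raise FixtureError(
            f"reclassified_variants.tsv: expected 18 rows, found {len(reclass)}"
        )
    for i, row in reclass.iterrows():
        for grp in ("aff", "unaff"):
            if int(row[f"{grp}_carrying"]) > int(row[f"{grp}_tested"]):
                raise FixtureError(
                    f"reclassified_variants.tsv: row {i} {row['cdna']}: "
                    f"{grp}_carrying > {grp}_tested"
                )

    return FixtureBundle(
        panel=panel,
        cohort_table=cohort,
        mutations=mutations,
        genotype_phenotype=gp,
        reclassification=reclass,
        inconsistent_cells=inconsistent,
    )


# ---------------------------------------------------------------------------
# Per-proband reconstructions of the aggregate tables

_DIAGNOSIS_BY_LABEL = {d.value: d for d in Diagnosis}

_CLASS_EXAMPLE_CDNA = {
    MutationClass.FRAMESHIFT_INSERTION: "c.3440_3441insTTCAGCTGTC",
    MutationClass.FRAMESHIFT_DELETION: "c.8525_8529del",
    MutationClass.STOPGAIN: "c.7477C>T",
    MutationClass.SPLICING: "c.6740-1G>A",
    MutationClass.MISSENSE: "c.5372G>A",
}


def reconstruct_cohort(bundle: FixtureBundle) -> list[Proband]:
    """Expand the diagnosis × result cross-tab into one Proband per case.

    Positive probands get a single likely-pathogenic FBN1 variant, VUS-only
    probands a single VUS, negatives none; this preserves exactly the
    information the cross-tab holds.
    """
    probands: list[Proband] = []
    body = bundle.cohort_table[bundle.cohort_table["diagnosis"] != "Total"]
    for _, row in body.iterrows():
        diagnosis = _DIAGNOSIS_BY_LABEL[row["diagnosis"]]
        short = "".join(w[0] for w in row["diagnosis"].split())
        spec = [
            ("pathogenic", PathogenicityTier.LIKELY_PATHOGENIC),
            ("vus", PathogenicityTier.VUS),
            ("negative", None),
        ]
        for col, tier in spec:
            for i in range(int(row[col])):
                variants = []
                if tier is not None:
                    variants = [
                        ClassifiedVariant(
                            gene="FBN1",
                            mutation_class=MutationClass.MISSENSE,
                            tier=tier,
                        )
                    ]
                probands.append(
                    Proband(
                        id=f"{short}-{col[:3]}-{i + 1:03d}",
                        diagnosis=diagnosis,
                        variants=variants,
                    )
                )
    return probands


def reconstruct_fbn1_cohort(bundle: FixtureBundle) -> list[Proband]:
    """Per-proband reconstruction of the genotype-phenotype table's sub-cells.

    Each (class, event) cell of count *n* and mean age *a* becomes *n*
    probands of age *a* carrying one pathogenic FBN1 variant of that class —
    the coarsest per-patient data consistent with the printed aggregate.
    """
    probands: list[Proband] = []
    leaf = bundle.genotype_phenotype[
        bundle.genotype_phenotype["mutation_class"] != ROLLUP_ROW
    ]
    for _, row in leaf.iterrows():
        mc = MutationClass(row["mutation_class"])
        event = AorticEvent(row["event"])
        for i in range(int(row["count"])):
            probands.append(
                Proband(
                    id=f"FBN1-{mc.value}-{event.value}-{i + 1}",
                    diagnosis=Diagnosis.MARFAN,
                    variants=[
                        ClassifiedVariant(
                            gene="FBN1",
                            mutation_class=mc,
                            tier=PathogenicityTier.PATHOGENIC,
                            cdna=_CLASS_EXAMPLE_CDNA.get(mc),
                        )
                    ],
                    aortic_event=event,
                    age_at_event=row["mean_age"],
                )
            )
    return probands


# ---------------------------------------------------------------------------
# Synthetic callset generator


class TruthLabel(str, Enum):
    TRUE_VARIANT = "true_variant"
    END_ARTIFACT = "end_of_amplicon_artifact"
    STRAND_ARTIFACT = "strand_bias_artifact"
    BLACKLISTED = "blacklisted_recurrent"
    HOTSPOT_NOCALL = "hotspot_nocall_site"


ARTIFACT_LABELS = {
    TruthLabel.END_ARTIFACT,
    TruthLabel.STRAND_ARTIFACT,
    TruthLabel.BLACKLISTED,
}


@dataclass(frozen=True)
class TruthRecord:
    chrom: str
    pos: int
    ref: str
    alt: str
    label: TruthLabel
    detail: str = "."


@dataclass(frozen=True)
class SimulationParams:
    """Callset composition and coordinate-frame geometry."""

    n_true: int = 20
    n_end_artifact: int = 10
    n_strand_artifact: int = 10
    n_blacklisted: int = 5
    n_hotspot_nocall: int = 5
    n_amplicons: int = 24
    amplicon_length: int = 150
    base_depth: int = 350  # matches the panel's observed mean depth scale
    end_margin: int = 5

    def __post_init__(self) -> None:
        for name in (
            "n_true",
            "n_end_artifact",
            "n_strand_artifact",
            "n_blacklisted",
            "n_hotspot_nocall",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_amplicons < 12 or self.amplicon_length < 60:
            raise ValueError("frame too small for the exon layout")


CONTIG = "panel1"

_NON_STOP_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in {"TAA", "TAG", "TGA"}
]


@dataclass
class SyntheticCallset:
    params: SimulationParams
    seed: int
    reference: dict[str, str]
    panel: PanelDefinition
    transcript: TranscriptModel
    hotspots: HotspotSet
    calls: list[VariantCall]
    truth: list[TruthRecord]
    blacklist: FalsePositiveList
    coverage: CoverageTrack

    def truth_by_key(self) -> dict[tuple[str, int, str, str], TruthRecord]:
        return {(t.chrom, t.pos, t.ref, t.alt): t for t in self.truth}

    def truth_tsv_text(self) -> str:
        lines = ["chrom\tpos\tref\talt\tlabel\tdetail"]
        for t in self.truth:
            lines.append(f"{t.chrom}\t{t.pos}\t{t.ref}\t{t.alt}\t{t.label.value}\t{t.detail}")
        return "\n".join(lines) + "\n"

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write the full file set (reference, panel, calls, coverage, truth)."""
        from .vcfio import write_calls

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {name: outdir / fn for name, fn in [
            ("reference", "reference.fa"),
            ("amplicons", "amplicons.bed"),
            ("transcript", "transcript.gp"),
            ("cds_fasta", "transcript_cds.fa"),
            ("vcf", "calls.vcf"),
            ("coverage", "coverage.bedgraph"),
            ("truth", "truth.tsv"),
            ("blacklist", "blacklist.tsv"),
        ]}
        seq = self.reference[CONTIG]
        with open(paths["reference"], "w") as fh:
            fh.write(f">{CONTIG}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
        with open(paths["amplicons"], "w") as fh:
            for a in self.panel.amplicons:
                fh.write(f"{a.chrom}\t{a.start}\t{a.end}\t{a.gene}\t{a.amplicon_id}\n")
        tm = self.transcript
        starts = ",".join(str(s) for s, _ in tm.exons) + ","
        ends = ",".join(str(e) for _, e in tm.exons) + ","
        with open(paths["transcript"], "w") as fh:
            fh.write(
                f"{tm.accession}\t{tm.chrom}\t{tm.strand}\t{tm.exons[0][0]}\t"
                f"{tm.exons[-1][1]}\t{tm.cds_start}\t{tm.cds_end}\t{len(tm.exons)}\t"
                f"{starts}\t{ends}\t0\t{tm.gene}\n"
            )
        with open(paths["cds_fasta"], "w") as fh:
            fh.write(f">{tm.accession}\n{tm.cds_sequence}\n")
        write_calls(paths["vcf"], self.calls, contigs={CONTIG: len(seq)})
        self.coverage.to_bedgraph(paths["coverage"])
        paths["truth"].write_text(self.truth_tsv_text())
        with open(paths["blacklist"], "w") as fh:
            fh.write("chrom\tpos\tref\talt\tnote\n")
            for chrom, pos, ref, alt in sorted(self.blacklist.keys):
                fh.write(f"{chrom}\t{pos}\t{ref}\t{alt}\trecurrent artifact (synthetic)\n")
        return paths


def _build_transcript(rng: np.random.Generator, params: SimulationParams, reference: list[str]) -> TranscriptModel:
    """Lay a 6-exon plus-strand CDS into amplicon interiors and patch the reference."""
    L = params.amplicon_length
    exon_len = 90
    exon_amps = [2 * i + 1 for i in range(6)]  # spread over the frame
    exons = []
    for k in exon_amps:
        start = k * L + 30
        exons.append((start, start + exon_len))
    n_codons = 6 * exon_len // 3  # 180
    codons = ["ATG"]
    body = [
        _NON_STOP_CODONS[i]
        for i in rng.integers(0, len(_NON_STOP_CODONS), size=n_codons - 2)
    ]
    # force a fixed complement of cysteine codons, spread over the body
    n_cys = max(8, params.n_hotspot_nocall + 2)
    cys_slots = rng.choice(len(body), size=n_cys, replace=False)
    for j, slot in enumerate(sorted(cys_slots)):
        body[slot] = "TGT" if j % 2 == 0 else "TGC"
    codons += body + ["TAA"]
    cds = "".join(codons)
    # patch the reference
    i = 0
    for s, e in exons:
        reference[s:e] = list(cds[i : i + (e - s)])
        i += e - s
    return TranscriptModel(
        gene="FBN1",
        accession="FBN1SYN.1",
        chrom=CONTIG,
        strand="+",
        exons=tuple(exons),
        cds_start=exons[0][0],
        cds_end=exons[-1][1],
        cds_sequence=cds,
    )


def generate_callset(
    params: SimulationParams | None = None,
    seed: int = 0,
    outdir: str | Path | None = None,
) -> SyntheticCallset:
    """Generate a reproducible truth-labelled callset on the synthetic frame."""
    params = params or SimulationParams()
    rng = np.random.default_rng(seed)
    L = params.amplicon_length
    contig_len = params.n_amplicons * L + 50

    reference = list(rng.choice(list("ACGT"), size=contig_len))
    transcript = _build_transcript(rng, params, reference)
    refseq = "".join(reference)

    genes = load_panel_definition(DATA_DIR / "panel_genes.tsv").genes
    amplicons = [
        Amplicon(CONTIG, i * L, (i + 1) * L, "FBN1", f"AMP{i + 1:03d}")
        for i in range(params.n_amplicons)
    ]
    panel = PanelDefinition(genes=genes, amplicons=amplicons)
    hotspots = cysteine_hotspots(transcript)

    used: set[int] = set()

    def claim(pool: list[int], width: int = 1) -> int:
        candidates = [
            p
            for p in pool
            if all(p + w not in used for w in range(-1, width + 1))
        ]
        pos = int(rng.choice(candidates))
        used.update(range(pos - 1, pos + width + 1))
        return pos

    interior_pool = [
        p
        for a in amplicons
        for p in range(a.start + 1 + params.end_margin, a.end - params.end_margin - 2)
        if p not in hotspots.positions
    ]
    end_pool = [
        p
        for a in amplicons
        for p in list(range(a.start + 1, a.start + params.end_margin + 1))
        + list(range(a.end - params.end_margin + 1, a.end + 1))
        if p not in hotspots.positions
    ]

    def other_base(b: str) -> str:
        return str(rng.choice([x for x in "ACGT" if x != b]))

    calls: list[VariantCall] = []
    truth: list[TruthRecord] = []

    def add(pos, ref, alt, depth, f, r, label, detail=".", genotype=GenotypeState.CALLED):
        calls.append(
            VariantCall(
                chrom=CONTIG,
                pos=pos,
                ref=ref,
                alt=alt,
                depth=depth,
                alt_forward=f,
                alt_reverse=r,
                genotype=genotype,
                sample="SAMPLE",
            )
        )
        truth.append(TruthRecord(CONTIG, pos, ref, alt, label, detail))

    def confident_support():
        depth = int(rng.integers(100, 2 * params.base_depth))
        alt_total = max(10, int(depth * rng.uniform(0.3, 0.6)))
        f = alt_total // 2
        return depth, f, alt_total - f

    # true variants: alternate SNV / insertion / deletion
    for i in range(params.n_true):
        pos = claim(interior_pool, width=2)
        base = refseq[pos - 1]
        depth, f, r = confident_support()
        if i % 3 == 0:
            add(pos, base, other_base(base), depth, f, r, TruthLabel.TRUE_VARIANT, "snv")
        elif i % 3 == 1:
            ins = "".join(rng.choice(list("ACGT"), size=int(rng.integers(1, 3))))
            add(pos, base, base + ins, depth, f, r, TruthLabel.TRUE_VARIANT, "insertion")
        else:
            dlen = int(rng.integers(1, 3))
            add(pos, refseq[pos - 1 : pos + dlen], base, depth, f, r, TruthLabel.TRUE_VARIANT, "deletion")

    # end-of-amplicon artifacts: SNVs caught only by the positional flag
    for _ in range(params.n_end_artifact):
        pos = claim(end_pool)
        base = refseq[pos - 1]
        depth, f, r = confident_support()
        add(pos, base, other_base(base), depth, f, r, TruthLabel.END_ARTIFACT)

    # strand-bias artifacts: indels violating one named predicate
    for i in range(params.n_strand_artifact):
        pos = claim(interior_pool, width=1)
        base = refseq[pos - 1]
        mode = str(rng.choice(["strand_reads", "strand_ratio"]))
        if mode == "strand_reads":
            f = int(rng.integers(0, 4))  # <= 3 on the forward strand
            r = int(rng.integers(10, 31))
        else:
            f = int(rng.integers(10, 21))
            r = int(rng.integers(4, max(5, int(0.65 * f)) + 1))  # ratio < 0.7
        depth = max(25, int((f + r) / rng.uniform(0.2, 0.5)))
        ins = str(rng.choice(list("ACGT")))
        add(pos, base, base + ins, depth, f, r, TruthLabel.STRAND_ARTIFACT, mode)

    # recurrent blacklisted artifacts: clean-looking support, known alleles
    blacklist_keys: set[tuple[str, int, str, str]] = set()
    for i in range(params.n_blacklisted):
        pos = claim(interior_pool, width=1)
        base = refseq[pos - 1]
        depth, f, r = confident_support()
        if i % 2 == 0:
            ref_a, alt_a = base, other_base(base)
        else:
            ref_a, alt_a = base, base + str(rng.choice(list("ACGT")))
        add(pos, ref_a, alt_a, depth, f, r, TruthLabel.BLACKLISTED)
        blacklist_keys.add((CONTIG, pos, ref_a, alt_a))

    # hotspot NoCall sites: one candidate record per chosen cysteine codon
    cys_codon_positions = sorted(hotspots.positions)
    codon_firsts = cys_codon_positions[:: 3]
    chosen = list(
        rng.choice(codon_firsts, size=min(params.n_hotspot_nocall, len(codon_firsts)), replace=False)
    )
    nocall_positions = sorted(int(p) for p in chosen)
    for pos in nocall_positions:
        base = refseq[pos - 1]
        add(
            pos,
            base,
            other_base(base),
            depth=5,
            f=1,
            r=1,
            label=TruthLabel.HOTSPOT_NOCALL,
            detail="nocall",
            genotype=GenotypeState.NOCALL,
        )

    order = np.argsort([c.pos for c in calls], kind="stable")
    calls = [calls[i] for i in order]
    truth = [truth[i] for i in order]

    # coverage: uniform base depth with dips at the NoCall sites
    boundaries = sorted({0, contig_len} | {p - 1 for p in nocall_positions} | {p for p in nocall_positions})
    intervals = []
    dip = set(nocall_positions)
    prev = 0
    for b in boundaries[1:]:
        depth = 5 if (prev + 1) in dip and b == prev + 1 else params.base_depth
        intervals.append((CONTIG, prev, b, depth))
        prev = b
    coverage = CoverageTrack(intervals=intervals)

    callset = SyntheticCallset(
        params=params,
        seed=seed,
        reference={CONTIG: refseq},
        panel=panel,
        transcript=transcript,
        hotspots=hotspots,
        calls=calls,
        truth=truth,
        blacklist=FalsePositiveList(keys=frozenset(blacklist_keys), provenance="synthetic"),
        coverage=coverage,
    )
    if outdir is not None:
        callset.write(outdir)
    return callset


# ---------------------------------------------------------------------------
# Filter evaluation


@dataclass
class FilterEvaluation:
    sensitivity: float  # labelled true variants retained
    specificity: float  # artifacts removed or flagged
    fp_rate_before: float  # artifact fraction among genotyped calls
    fp_rate_after: float  # artifact fraction among retained genotyped calls
    per_stage: pd.DataFrame  # drop counts: status x truth label

    def __str__(self) -> str:
        return (
            f"sensitivity={self.sensitivity:.3f} specificity={self.specificity:.3f} "
            f"FP rate {100 * self.fp_rate_before:.1f}% -> {100 * self.fp_rate_after:.1f}%"
        )


def evaluate_filters(
    cs: SyntheticCallset, verdicts: Sequence[TriageVerdict]
) -> FilterEvaluation:
    """Score a triage run against the truth labels.

    NoCall surveillance records are not genotyped calls, so they are excluded
    from the call-level rates (they are evaluated by the QC alerts instead).
    An end-of-amplicon artifact counts as handled for specificity when it is
    either dropped or carries the positional flag.
    """
    truth = cs.truth_by_key()
    pairs = []
    for v in verdicts:
        key = v.call.key()
        if key not in truth:
            raise ValueError(f"verdict for unknown call {key}")
        pairs.append((truth[key], v))
    if len(pairs) != len(cs.truth):
        raise ValueError(
            f"verdict count {len(pairs)} does not match truth count {len(cs.truth)}"
        )

    genotyped = [
        (t, v) for t, v in pairs if t.label is not TruthLabel.HOTSPOT_NOCALL
    ]
    n_true = sum(1 for t, _ in genotyped if t.label is TruthLabel.TRUE_VARIANT)
    n_artifact = sum(1 for t, _ in genotyped if t.label in ARTIFACT_LABELS)
    retained = [(t, v) for t, v in genotyped if v.retained]
    retained_true = sum(1 for t, _ in retained if t.label is TruthLabel.TRUE_VARIANT)
    retained_artifacts = sum(1 for t, _ in retained if t.label in ARTIFACT_LABELS)
    handled = sum(
        1
        for t, v in genotyped
        if t.label in ARTIFACT_LABELS
        and (not v.retained or "amplicon_end_proximal" in v.flags)
    )

    per_stage = (
        pd.DataFrame(
            [(v.status.value, t.label.value) for t, v in genotyped],
            columns=["status", "label"],
        )
        .value_counts()
        .unstack(fill_value=0)
    )

    return FilterEvaluation(
        sensitivity=retained_true / n_true if n_true else 1.0,
        specificity=handled / n_artifact if n_artifact else 1.0,
        fp_rate_before=n_artifact / len(genotyped) if genotyped else 0.0,
        fp_rate_after=retained_artifacts / len(retained) if retained else 0.0,
        per_stage=per_stage,
    )
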