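# Methods

This note documents the models, rules and numerical choices behind
`aortapanel`, and what the synthetic benchmark does and does not show.

## Coordinate and format conventions

Variant and hotspot positions are 1-based inclusive (VCF convention);
interval files — amplicon BED, genePred exon bounds, BED-graph coverage —
are 0-based half-open.  Conversion happens only in the I/O layer.  Transcript
models are genePred-extended rows (name, chrom, strand, txStart, txEnd,
cdsStart, cdsEnd, exonCount, exonStarts, exonEnds, score, gene symbol) plus
a FASTA of the spliced CDS keyed by accession; genePred was chosen over GFF3
because one line per transcript is sufficient for a fixed single-canonical-
transcript panel.  One canonical transcript per gene is assumed throughout;
multi-transcript annotation is out of scope.

Transcript validation enforces: non-overlapping ordered exons, CDS length
divisible by 3, CDS sequence length equal to the exonic CDS extent, and no
internal stop codon.  Minus-strand genes are supported: codon assembly walks
the genome in reverse, but all reported positions stay genomic.

## Triage filters

**Allele fraction** is defined as (alt forward + alt reverse) / total depth;
the sequencing-platform report gives no formula, so the conventional
definition is used.  **Strand balance** is assessed on alt-allele reads only
(not total strand depth): both strands must contribute more than 3 reads and
the two counts must lie within a factor of 0.7 of each other.  All
thresholds are strict inequalities — a depth of exactly 20 fails — because
the operating point is printed as strict (">20x", ">10%", ">3", ">0.7").
A zero-depth indel short-circuits to "no coverage" without division.

The indel-confidence rule applies to insertions/deletions only; SNVs bypass
it.  The three-predicate confidence language is attached specifically to
frameshift/non-frameshift indels, which are the error mode of
semiconductor-sequencing homopolymers; extending it to SNVs would discard
well-supported substitutions for no documented reason.

**Stage order** is fixed as frequency → blacklist → indel-confidence so the
recorded drop reason per call is reproducible.  The retained set is
order-invariant (each stage is a pure predicate), so the order only affects
attribution.

**Blacklist keys** are normalized to left-aligned minimal representation
(vt-style: trim shared suffix, roll left through repeat tracts, trim shared
prefix) before lookup, so the same indel spelled at different anchors in a
homopolymer matches.  Normalization requires reference context and lives
behind an explicit `reference` argument.

**Amplicon-end proximity is a flag, not a drop.**  Recurrent artifacts
cluster at amplicon ends (degenerate primers, mapping error), but site-level
removal is what the blacklist is for; a positional kill rule would also
remove true variants that merely happen to sit near an end.  The 5-base
margin is configurable and is an extrapolation, not a reported constant.  A
call is flagged only when it is end-proximal in *every* covering amplicon —
interior support from one overlapping amplicon rescues it.  Calls outside
all amplicons get an `off_target` flag instead.

**Population frequency**: maximum MAF across the population databases is
consumed as a single pre-joined annotation column; above 1 % disqualifies
(autosomal-dominant rare disease), absent keeps.  Multi-allelic records are
split into biallelic calls before any stage.

## Coverage QC and hotspot surveillance

Mean depth is base-weighted over the merged amplicon footprint; bases the
coverage track does not mention count as zero.  The callable threshold is
20× and is shared (single constant) with the low-coverage exon rule and the
NoCall-by-absence rule.  An exon is listed for confirmation when *any* base
is below threshold, and the confirmation unit is the exon, matching
confirmatory Sanger practice.

"NoCall" is defined as: the caller emitted a no-genotype record at the
position, **or** no record exists and depth is below the callable threshold.
The platform term is otherwise undefined; this definition covers both
observable cases.  Hotspot alerts are restricted by construction to the
hotspot set (every base of every TGT/TGC codon of the canonical *FBN1*
transcript) and name the enclosing exon.

## Classification rule table

The five tiers are ordered benign < likely benign < VUS < likely pathogenic
< pathogenic.  Clinical guidelines enumerate evidence axes but not a
combining algorithm, so a minimal deterministic table is defined:

1. MAF > 1 % → **benign** (dominates everything).
2. Protein-null class (stopgain, frameshift, canonical ±1/±2 splicing,
   start loss): **pathogenic** when absent from population databases,
   **likely pathogenic** when present but rare (≤ 1 %).
3. Missense absent from databases: **likely pathogenic** when it destroys or
   creates an *FBN1* cysteine, or when previously reported
   (functional/segregation literature); otherwise VUS.
4. Rare but database-present with no supporting evidence → **likely
   benign**; conservation support, ≥ 2 damaging in-silico predictions, or
   cysteine involvement keep it at **VUS** (supporting evidence acts only as
   a tie-breaker between adjacent tiers, never as a sole promoter).
5. A confirmed de novo occurrence promotes a VUS to **likely pathogenic**.
   It does not push likely pathogenic to pathogenic: in the reference
   mutation set, confirmed de novo cysteine substitutions are reported as
   likely pathogenic, so de novo status behaves as supporting, not strong,
   evidence.
6. Everything else → **VUS**.

Splicing is positional only — intronic offset magnitude 1 or 2.  Deeper
intronic changes classify as `other`.  Duplications group with insertions;
deletion-insertions resolve by the sign of the net length change (net 0 →
non-frameshift indel), except that a delins whose protein consequence is a
clean single-residue substitution is missense.  Start loss is its own class,
excluded from the truncating/splicing-versus-missense dichotomy but still
counted as null evidence.  "Inherited from mother/father" without the
parent's affection status maps to de novo *unknown*.

HGVS parsing is lenient by default: a malformed protein string (the fixture
contains one, `p.HisiSer656fs`) keeps its legible semantics (trailing `fs`)
and carries an anomaly flag, letting classification fall back on the cDNA
string; strict mode raises instead.  Exon/intron labels in annotation tables
are ignored in favour of the HGVS string itself (the fixture has rows whose
printed label contradicts the cDNA position).

On the packaged 87-row mutation fixture the rule table reproduces 86/87
printed tiers (98.9 %).  The single mismatch, *COL3A1* c.2932G>C
p.Gly978Arg (printed likely pathogenic, rule table VUS), rests on collagen
Gly-X-Y domain context that the annotation columns do not encode; it is
asserted as a known gap in the tests rather than special-cased in the rule.

## Segregation reclassification

One observation object per variant: affected relatives tested/carrying and
unaffected relatives tested/carrying.  Discordance = affected non-carriers +
unaffected carriers.

* No discordance: tier unchanged; carriage by ≥ 2 affected relatives
  promotes VUS → likely pathogenic.
* Any discordance caps (likely) pathogenic at VUS, consuming one discordant
  observation.
* Residual discordance pushes a VUS to the benign side: exactly one residual
  unaffected carrier → likely benign; an affected non-carrier or ≥ 2
  residual discordant observations → benign.
* A likely benign tier with discordance demotes to benign.
* Zero relatives tested is a precondition violation (error).

The published reclassification table prints outcomes (18 rows, all changed)
but not pedigree counts, so the fixture encodes reconstructed observation
counts consistent with each printed outcome and case narrative (an affected
sibling non-carrier for the *FBN1* Cys476Tyr downgrade; a healthy carrier
father for the *TGFBR2* Arg381Pro downgrade); the fixture header marks these
columns as reconstructions.  The step sizes above are house policy chosen as
the minimal monotone rule reproducing all 18 printed outcomes, including the
likely-pathogenic → benign rows (which require more than one discordant
observation).

## Cohort reporting

Result per proband is best-variant dominance: any tier ≥ likely pathogenic →
positive; else any VUS → VUS-only; else negative.  Percentages use the full
cohort denominator with half-up rounding to one decimal (`round_half_up`,
ties away from zero — banker's rounding would disagree with printed clinical
tables).  Probands without clinical information contribute to the yield
table but are excluded from the genotype-phenotype table.  A proband with
two causal *FBN1* variants is counted once under the most severe class
(stopgain < frameshift del < frameshift ins < splicing < start loss <
missense in severity order) with a logged warning.  Start-loss and
non-frameshift-indel classes report in an `other` row rather than being
forced into the four truncating/splicing rows.  The truncating+splicing
rollup mean age is the count-weighted mean of the sub-cells, rounded half-up
to one decimal.

The fixture of the published genotype-phenotype table carries one internal
inconsistency: the printed aneurysm rollup age (25.6 y) is not the weighted
mean of its printed sub-rows (27.0 y).  The loader verifies all other cells,
requires this one to be explicitly flagged `age_inconsistent`, and the
implementation reports the computed weighted mean.

Aggregate tables are reproduced from per-proband reconstructions: each
cross-tab cell of count *n* (and mean age *a*) is expanded into *n* probands
(each at age *a*) — the coarsest per-patient dataset consistent with the
printed aggregates.  Equal ages within a cell preserve every cell mean and
all weighted rollups exactly.

## Synthetic callset generator

The generator emulates the *artifact structure* of amplicon panel data, not
its read-level error model.  Frame: one contig (`panel1`), 24 non-overlapping
150 bp amplicons, a plus-strand 6-exon transcript (90 bp exons laid into
amplicon interiors, 180 codons) whose CDS is guaranteed stop-free with a
forced complement of cysteine codons; reference bases outside exons are
uniform random.  Default composition (20 true variants, 10 end artifacts,
10 strand-bias artifacts, 5 blacklisted recurrent alleles, 5 hotspot NoCall
sites) keeps every artifact class populated while the whole benchmark runs
in well under a second; depth is drawn around 350×, the panel's
characteristic mean depth scale.

By construction: every true-variant indel satisfies all three confidence
predicates (alt reads split near-evenly across strands, fraction 0.3–0.6,
depth ≥ 100); every strand-bias artifact violates exactly one named strand
predicate (≤ 3 reads on one strand, or ratio < 0.7 with both strands > 3 —
the violated predicate is recorded in the truth table); end artifacts are
clean-looking SNVs placed within the flag margin; blacklisted alleles are
clean-looking but keyed on the generated blacklist; NoCall sites are
no-genotype records at cysteine hotspot bases with a matching coverage dip.
Everything is a pure function of (params, seed); outputs round-trip through
VCF/BED-graph/TSV losslessly.

Filter evaluation excludes NoCall records from call-level rates (they are
surveillance records, scored by the QC alerts).  The false-positive rate is
the artifact fraction among surviving genotyped calls; specificity counts an
end artifact as handled when it is dropped *or* flagged.  On this benchmark
full triage strictly lowers the false-positive rate at 100 % true-variant
sensitivity — a directional property.  The production pipeline's published
before/after false-positive rates are **not** reproducible here: their
denominators and per-sample validation data are unavailable, so no attempt
is made to match those two numbers.

## Known limitations

* The synthetic benchmark's artifacts are constructed to violate the filters
  they are named for; passing it shows the filters implement their
  definitions, not that the thresholds are optimal for real Ion Torrent
  data.
* The classifier encodes prior reports as a PMID presence bit; report
  strength (functional vs. segregation, study quality) is not modelled, which
  is exactly where the one fixture mismatch comes from.
* Segregation observation counts in the reclassification fixture are
  reconstructions, not published data.
* No genomic-HGVS validation against a reference sequence; the HGVS strings
  are trusted as printed.
* Real panel coordinates are not distributed with the package; users supply
  their own amplicon BED and transcript models, while fixtures and the
  simulator use the synthetic frame.
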