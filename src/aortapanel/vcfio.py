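"""VCF reading/writing for triage, via pysam.

Alt-allele strand counts are platform-specific.  The reader tries, in order:

1. per-sample FORMAT ``SAF``/``SAR`` (Number=A) — Ion Torrent convention;
2. INFO ``SAF``/``SAR``;
3. per-sample FORMAT ``ADF``/``ADR`` (Number=R, bcftools convention; entry
   ``i+1`` belongs to alt ``i``).

Multi-allelic records are decomposed into biallelic calls on read.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pysam

from .variant_filtering import GenotypeState, TriageVerdict, VariantCall


def _as_tuple(value) -> tuple:
    if value is None:
        return ()
    if isinstance(value, (tuple, list)):
        return tuple(value)
    return (value,)


def _strand_counts(rec: pysam.VariantRecord, sample, n_alts: int):
    fmt = rec.samples[sample] if sample is not None else None
    if fmt is not None and "SAF" in fmt and fmt.get("SAF") is not None:
        return _as_tuple(fmt["SAF"]), _as_tuple(fmt["SAR"])
    if "SAF" in rec.info:
        return _as_tuple(rec.info["SAF"]), _as_tuple(rec.info["SAR"])
    if fmt is not None and "ADF" in fmt and fmt.get("ADF") is not None:
        adf, adr = _as_tuple(fmt["ADF"]), _as_tuple(fmt["ADR"])
        return adf[1 : 1 + n_alts], adr[1 : 1 + n_alts]
    raise KeyError(
        f"{rec.chrom}:{rec.pos}: no alt strand counts (need SAF/SAR or ADF/ADR)"
    )


def read_calls(path: str | Path) -> list[VariantCall]:
    """Load a (single-sample) VCF into biallelic VariantCalls."""
    calls: list[VariantCall] = []
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        sample = samples[0] if samples else None
        for rec in vf:
            alts = rec.alts or ()
            fmt = rec.samples[sample] if sample is not None else None
            if fmt is not None and fmt.get("DP") is not None:
                depth = int(fmt["DP"])
            elif "DP" in rec.info:
                depth = int(rec.info["DP"])
            else:
                depth = 0
            gt = fmt.get("GT") if fmt is not None else None
            genotype = (
                GenotypeState.NOCALL
                if gt is None or all(a is None for a in gt)
                else GenotypeState.CALLED
            )
            if not alts or alts == (None,):
                continue
            saf, sar = _strand_counts(rec, sample, len(alts))
            for i, alt in enumerate(alts):
                calls.append(
                    VariantCall(
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=str(alt),
                        depth=depth,
                        alt_forward=int(saf[i] or 0),
                        alt_reverse=int(sar[i] or 0),
                        genotype=genotype,
                        sample=sample,
                    )
                )
    return calls


def _build_header(
    contigs: Mapping[str, int], sample: str = "SAMPLE"
) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for name, length in contigs.items():
        header.contigs.add(name, length=length)
    header.add_line(
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">'
    )
    header.add_line(
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">'
    )
    header.add_line(
        '##FORMAT=<ID=SAF,Number=A,Type=Integer,Description="Alt allele forward strand reads">'
    )
    header.add_line(
        '##FORMAT=<ID=SAR,Number=A,Type=Integer,Description="Alt allele reverse strand reads">'
    )
    header.add_line(
        '##FILTER=<ID=DropIndel,Description="Indel failing depth/allele-fraction/strand-balance confidence">'
    )
    header.add_line(
        '##FILTER=<ID=blacklisted,Description="Recurrent false-positive allele">'
    )
    header.add_line(
        '##FILTER=<ID=frequency_filtered,Description="Population MAF above threshold">'
    )
    header.add_line(
        '##INFO=<ID=TRIAGE_FLAGS,Number=.,Type=String,Description="Advisory triage flags">'
    )
    header.add_sample(sample)
    return header


def write_calls(
    path: str | Path,
    calls: Sequence[VariantCall],
    contigs: Mapping[str, int],
    verdicts: Sequence[TriageVerdict] | None = None,
) -> None:
    """Write calls (optionally with triage status in FILTER) as uncompressed VCF."""
    sample = next((c.sample for c in calls if c.sample), "SAMPLE")
    header = _build_header(contigs, sample=sample)
    by_call = {}
    if verdicts is not None:
        by_call = {id(v.call): v for v in verdicts}
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for call in calls:
            rec = out.new_record(
                contig=call.chrom,
                start=call.pos - 1,
                alleles=(call.ref, call.alt),
            )
            fmt = rec.samples[sample]
            fmt["GT"] = (
                (None, None) if call.genotype is GenotypeState.NOCALL else (0, 1)
            )
            fmt["DP"] = call.depth
            fmt["SAF"] = (call.alt_forward,)
            fmt["SAR"] = (call.alt_reverse,)
            verdict = by_call.get(id(call))
            if verdict is not None:
                if verdict.retained:
                    rec.filter.add("PASS")
                else:
                    rec.filter.add(verdict.status.value)
                if verdict.flags:
                    rec.info["TRIAGE_FLAGS"] = tuple(sorted(verdict.flags))
            out.write(rec)


def write_triage_report(path: str | Path, verdicts: Sequence[TriageVerdict]) -> None:
    """One row per call: identity, status, reasons, flags (TSV)."""
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tref\talt\tstatus\treasons\tflags\n")
        for v in verdicts:
            c = v.call
            fh.write(
                f"{c.chrom}\t{c.pos}\t{c.ref}\t{c.alt}\t{v.status.value}\t"
                f"{';'.join(v.reasons) or '.'}\t{';'.join(sorted(v.flags)) or '.'}\n"
            )
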