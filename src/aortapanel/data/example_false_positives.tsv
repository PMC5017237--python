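# Example recurrent false-positive list (format illustration for `aortapanel triage --blacklist`).
# Keys are normalized (left-aligned, minimal) chrom/pos/ref/alt tuples on the user's own
# coordinate frame; this example uses the synthetic single-contig frame of the simulator.
chrom	pos	ref	alt	note
panel1	151	A	AT	recurrent homopolymer insertion at amplicon junction
panel1	902	CT	C	recurrent deletion, degenerate primer
panel1	1733	G	A	recurrent SNV artifact
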