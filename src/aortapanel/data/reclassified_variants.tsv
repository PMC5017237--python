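# Segregation observation columns (aff_tested, aff_carrying, unaff_tested, unaff_carrying)
# are RECONSTRUCTED encodings chosen to be consistent with the printed reclassification
# outcomes and case narratives; they are not reported observation counts.
gene	transcript	location	cdna	protein	called	reclassified	basis	popfreqmax	pmid	aff_tested	aff_carrying	unaff_tested	unaff_carrying
COL3A1	NM_000090	exon48	c.3776C>T	p.Ala1259Val	VUS	Benign	Family segregation	0.0017	22001912	1	0	0	0
FBN1	NM_000138	exon25	c.2953G>A	p.Gly985Arg	Likely Pathogenic	Benign	Family segregation	.	11700157	1	0	2	2
FBN1	NM_000138	exon66	c.8308C>T	p.His2770Tyr	VUS	Benign	Family segregation	0.0001	.	0	0	2	2
FBN1	NM_000138	exon12	c.1427G>A	p.Cys476Tyr	Likely Pathogenic	VUS	Family segregation	.	.	1	0	0	0
FBN1	NM_000138	exon53	c.6380A>G	p.Asp2127Gly	VUS	Benign	Family segregation	.	.	1	0	0	0
FBN1	NM_000138	exon62	c.7627A>C	p.Asn2543His	VUS	Benign	Family segregation	.	.	1	0	1	1
FBN1	NM_000138	exon50	c.6050G>A	p.Cys2017Tyr	Likely Pathogenic	Benign	Family segregation	.	.	1	0	2	2
FBN1	NM_000138	exon59	c.7231G>A	p.Asp2411Asn	VUS	Benign	Family segregation	.	.	1	0	0	0
MYH11	NM_001040114	exon20	c.2293C>A	p.Pro765Thr	VUS	Benign	Family segregation	0.002	.	0	0	2	2
MYH11	NM_001040114	exon31	c.4090G>A	p.Glu1364Lys	VUS	Benign	Family segregation	0.0001	.	1	0	0	0
MYLK	NM_053025	exon10	c.998C>T	p.Pro333Leu	VUS	Benign	Family segregation	.	.	1	0	1	1
NOTCH1	NM_017617	exon34	c.6351C>A	p.Asn2117Lys	VUS	Benign	Family segregation	0.0004	.	1	0	0	0
NOTCH1	NM_017617	exon21	c.3401A>G	p.Gln1134Arg	VUS	Benign	Family segregation	.	.	0	0	2	2
NOTCH1	NM_017617	exon21	c.3402G>C	p.Gln1134His	VUS	Benign	Family segregation	.	.	1	0	0	0
SMAD3	NM_005902	exon1	c.5C>T	p.Ser2Leu	VUS	Benign	Family segregation	.	.	1	0	0	0
SMAD3	NM_005902	exon1	c.147_155del	p.49_51del	VUS	Likely Benign	Family segregation	.	.	0	0	1	1
SMAD4	NM_005359	exon6	c.700A>C	p.Ser234Arg	VUS	Benign	Family segregation	0.00011	.	1	0	0	0
TGFBR2	NM_001024847	exon5	c.1142G>C	p.Arg381Pro	Likely Pathogenic	VUS	Family segregation	.	16283890	0	0	1	1
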