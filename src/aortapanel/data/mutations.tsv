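gene	transcript	location	cdna	protein	de_novo	pathogenicity	pmid
ACTA2	NM_001613	exon7	c.773G>A	p.Arg258His	NA	Likely Pathogenic	19409525
ACTA2	NM_001613	exon2	c.116G>A	p.Arg39His	NA	Likely Pathogenic	19409525
COL3A1	NM_000090	exon41	c.2932G>C	p.Gly978Arg	NA	Likely Pathogenic	.
FBN1	NM_000138	exon33	c.4022A>G	p.Asn1341Ser	NA	Likely Pathogenic	10464652
FBN1	NM_000138	exon17	c.2055C>G	p.Cys685Trp	NA	Likely Pathogenic	12203987
FBN1	NM_000138	intron55	c.6740-1G>A	.	De novo	Pathogenic	.
FBN1	NM_000138	exon47	c.5788G>C	p.Asp1930His	NA	Likely Pathogenic	17657824
FBN1	NM_000138	exon29	c.3496T>C	p.Cys1166Arg	NA	Likely Pathogenic	.
FBN1	NM_000138	exon28	c.3440_3441insTTCAGCTGTC	p.Ser1147fs	NA	Pathogenic	.
FBN1	NM_000138	exon40	c.4897_4898insCGCT	p.Cys1633fs	NA	Pathogenic	.
FBN1	NM_000138	intron55	c.6739+1G>T	.	NA	Pathogenic	.
FBN1	NM_000138	exon33	c.3995delA	p.Asn1332fs	Inherited from mother	Pathogenic	.
FBN1	NM_000138	exon64	c.7871A>C	p.Asn2624Thr	NA	Likely Pathogenic	19293843
FBN1	NM_000138	intron13	c.1589-1G>A	.	NA	Pathogenic	.
FBN1	NM_000138	exon54	c.6569G>A	p.Cys2190Tyr	NA	Likely Pathogenic	.
FBN1	NM_000138	exon61	c.7477C>T	p.Gln2493Ter	NA	Pathogenic	.
FBN1	NM_000138	exon7	c.643C>T	p.Arg215Ter	NA	Pathogenic	11139245
FBN1	NM_000138	exon58	c.7039_7040del	p.Met2347fs	NA	Pathogenic	.
FBN1	NM_000138	exon37	c.4527dupT	p.Ile1510fs	NA	Pathogenic	.
FBN1	NM_000138	exon13	c.1481G>A	p.Cys494Tyr	NA	Likely Pathogenic	24501682
FBN1	NM_000138	exon66	c.8525_8529del	p.Leu2842fs	Inherited from mother	Pathogenic	.
FBN1	NM_000138	exon28	c.3352C>T	p.Gln1118Ter	De novo	Pathogenic	.
FBN1	NM_000138	exon42	c.5162G>A	p.Cys1721Tyr	NA	Likely Pathogenic	9399842
FBN1	NM_000138	exon37	c.4532G>T	p.Cys1511Phe	De novo	Likely Pathogenic	.
FBN1	NM_000138	exon40	c.4831delC	p.Gln1611fs	NA	Pathogenic	.
FBN1	NM_000138	exon62	c.7606G>A	p.Gly2536Arg	NA	Likely Pathogenic	11524736
FBN1	NM_000138	exon44	c.5372G>A	p.Cys1791Tyr	NA	Likely Pathogenic	11700157
FBN1	NM_000138	exon63	c.7754T>C	p.Ile2585Thr	NA	Likely Pathogenic	10464652
FBN1	NM_000138	exon64	c.7955G>A	p.Cys2652Tyr	NA	Likely Pathogenic	17627385
FBN1	NM_000138	exon13	c.1585C>T	p.Arg529Ter	NA	Pathogenic	17663468
FBN1	NM_000138	exon31	c.3778G>T	p.Glu1260Ter	NA	Pathogenic	10464652
FBN1	NM_000138	exon58	c.7010_7011delinsCAC	p.Gly2337fs	NA	Pathogenic	.
FBN1	NM_000138	exon50	c.6071G>A	p.Cys2024Tyr	NA	Likely Pathogenic	.
FBN1	NM_000138	exon33	c.4081_4082delinsAA	p.Cys1361Asn	NA	Likely Pathogenic	.
FBN1	NM_000138	exon49	c.6000C>A	p.Cys2000Ter	NA	Pathogenic	.
FBN1	NM_000138	exon49	c.4544_4546delinsAGAT	p.Pro1515fs	NA	Pathogenic	.
FBN1	NM_000138	intron21	c.2540-2A>G	.	NA	Pathogenic	.
FBN1	NM_000138	intron49	c.6037+2T>C	.	NA	Pathogenic	.
FBN1	NM_000138	exon24	c.2740T>C	p.Cys914Arg	NA	Likely Pathogenic	.
FBN1	NM_000138	exon16	c.1884C>A	p.Cys628Ter	NA	Pathogenic	12068374
FBN1	NM_000138	exon15	c.1794C>A	p.Cys598Ter	NA	Pathogenic	.
FBN1	NM_000138	exon53	c.6446A>G	p.Tyr2149Cys	NA	Likely Pathogenic	24793577
FBN1	NM_000138	intron27	c.3337+1G>A	.	De novo	Pathogenic	.
FBN1	NM_000138	exon45	c.5434T>C	p.Cys1812Arg	De novo	Likely Pathogenic	19533785
FBN1	NM_000138	intron16	c.1960+1delG	.	De novo	Pathogenic	.
FBN1	NM_000138	exon45	c.5455C>T	p.Gln1819Ter	NA	Pathogenic	.
FBN1	NM_000138	exon35	c.4331G>A	p.Cys1444Tyr	NA	Likely Pathogenic	.
FBN1	NM_000138	exon21	c.2433C>G	p.Cys811Trp	NA	Likely Pathogenic	15241795
FBN1	NM_000138	exon64	c.7868dupA	p.His2623fs	Inherited from mother	Pathogenic	.
FBN1	NM_000138	exon48	c.5873G>A	p.Cys1958Tyr	NA	Likely Pathogenic	21907952
FBN1	NM_000138	exon63	c.7711T>C	p.Cys2571Arg	NA	Likely Pathogenic	16222657
FBN1	NM_000138	exon56	c.6867T>A	p.Cys2289Ter	NA	Pathogenic	.
FBN1	NM_000138	intron28	c.3464-2A>G	.	NA	Pathogenic	.
FBN1	NM_000138	exon12	c.1374T>A	p.Tyr458Ter	De novo	Pathogenic	.
FBN1	NM_000138	exon40	c.4897T>C	p.Cys1633Arg	NA	Likely Pathogenic	.
FBN1	NM_000138	exon11	c.1285C>T	p.Arg429Ter	NA	Pathogenic	11933199
FBN1	NM_000138	exon17	c.1968_1969dupCA	p.HisiSer656fs	NA	Pathogenic	.
FBN1	NM_000138	exon13	c.1561_1562insCAGA	p.Ser521fs	NA	Pathogenic	.
FBN1	NM_000138	exon35	c.4292G>A	p.Cys1431Tyr	NA	Likely Pathogenic	21542060
FBN1	NM_000138	intron48	c.5918-1G>A	.	De novo	Pathogenic	.
FBN1	NM_000138	intron48	c.5917+2T>C	.	NA	Pathogenic	.
FBN1	NM_000138	exon14	c.1633C>T	p.Arg545Cys	NA	Likely Pathogenic	9338581
FBN1	NM_000138	exon9	c.897T>G	p.Cys299Trp	NA	Likely Pathogenic	.
FBN1	NM_000138	exon7	c.640G>A	p.Gly214Ser	NA	Likely Pathogenic	15733436
FBN1	NM_000138	exon45	c.5540G>T	p.Cys1847Phe	Inherited from father	Likely Pathogenic	.
FBN1	NM_000138	exon64	c.7921C>T	p.Gln2641Ter	NA	Pathogenic	.
FBN1	NM_000138	intron28	c.3463+1G>T	.	NA	Pathogenic	.
FBN1	NM_000138	exon27	c.3217delG	p.Glu1073fs	NA	Pathogenic	.
FBN1	NM_000138	exon25	c.2987G>A	p.Cys996Tyr	NA	Likely Pathogenic	.
FBN1	NM_000138	exon56	c.6806T>C	p.Ile2269Thr	NA	Likely Pathogenic	10464652
FBN1	NM_000138	exon66	c.8547T>G	p.Tyr2849Ter	NA	Pathogenic	21034599
FBN1	NM_000138	exon66	c.6296G>A	p.Cys2099Tyr	NA	Likely Pathogenic	.
FBN1	NM_000138	exon2	c.3G>A	p.Met1Ile	NA	Pathogenic	.
FBN1	NM_000138	exon66	c.1098G>C	p.Trp366Cys	NA	Likely Pathogenic	.
FBN1	NM_000138	exon66	c.5841C>A	p.Cys1947Ter	NA	Pathogenic	.
FBN1	NM_000138	exon6	c.529T>C	p.Cys177Arg	De novo	Likely Pathogenic	16222657
FBN1	NM_000138	exon42	c.5065+1G>A	.	NA	Pathogenic	17627385
FBN1	NM_000138	exon62	c.7636_7642del	p.Gly2546fs	NA	Pathogenic	.
FBN1	NM_000138	exon3	c.184C>T	p.Arg62Cys	NA	Likely Pathogenic	11826022
FBN1	NM_000138	exon34	c.4096G>A	p.Glu1366Lys	NA	Likely Pathogenic	14695540
FBN1	NM_000138	exon48	c.5788+1G>A	.	NA	Pathogenic	11702223
FBN1	NM_000138	exon53	c.6431A>G	p.Asn2144Ser	NA	Likely Pathogenic	8504310
MYH11	NM_001040114	intron33	c.4599+1G>A	.	NA	Pathogenic	21937134
SLC2A10	NM_030777	exon2	c.1053_1054del	p.Ser351fs	NA	Pathogenic	.
TGFBR1	NM_004612	exon9	c.1459C>T	p.Arg487Trp	NA	Likely Pathogenic	16928994
TGFBR1	NM_004612	exon4	c.678_680del	p.226_227del	De novo	Likely Pathogenic	.
TGFBR2	NM_001024847	exon7	c.1524dupT	p.Cys508fs	NA	Pathogenic	.
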