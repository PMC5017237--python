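symbol	locus	protein	disease	exons	amplicons	coverage
ACTA2	10q22-q24	actin, alpha 2, smooth muscle, aorta	TAAD	10	15	1
COL3A1	2q31	collagen, type III, alpha 1	vEDS	51	66	0.998
FBN1	15q21.1	fibrillin 1	Marfan, MASS, Mitral valve prolapse syndrome, Ectopia lentis syndrome, SGS	66	106	1
FBN2	5q23-q31	fibrillin-2	CCA	65	99	1
MYH11	16p13.13-p13.12	myosin-11	TAAD	43	61	0.971
MYLK	3q21	myosin light chain kinase, smooth muscle	TAAD	34	66	0.983
NOTCH1	9q34.3	neurogenic locus notch homolog protein 1	TAAD	34	78	0.892
PRKG1	10q11.2	cGMP-dependent protein kinase 1	TAAD	21	23	0.934
SKI	1p36.33	ski oncogene	SGS	8	19	0.971
SLC2A10	20q13.1	solute carrier family 2, facilitated glucose transporter member 10	Arterial tortuosity syndrome	8	26	0.977
SMAD3	15q22.33	mothers against decapentaplegic homolog 3	LDS, TAAD	13	46	0.922
SMAD4	18q21.1	mothers against decapentaplegic homolog 4	TAAD	12	54	1
TGFB2	1q41	transforming growth factor beta-2	LDS	8	36	0.922
TGFBR1	9q33-q34	TGF-beta receptor type-1	LDS, TAAD	11	39	1
TGFBR2	3p22	TGF-beta receptor type-2	LDS, TAAD	9	29	1
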