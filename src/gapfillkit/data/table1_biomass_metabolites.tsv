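name	biocyc_id	pre_gap_fill
(2E,6E)-farnesyl diphosphate	FARNESYL-PP
1-deoxy-D-xylulose 5-phosphate	DEOXYXYLULOSE-5P
2-C-methyl-D-erythritol 4-phosphate	2-C-METHYL-D-ERYTHRITOL-4-PHOSPHATE
2-C-methyl-D-erythritol-2,4-cyclodiphosphate	2C-METH-D-ERYTHRITOL-CYCLODIPHOSPHATE
2-phospho-4-(cytidine 5'-diphospho)-2-C-methyl-D-erythritol	2-PHOSPHO-4-CYTIDINE-5-DIPHOSPHO-2-C-MET
ADP	ADP	X
ADP-alpha-D-glucose	ADP-D-GLUCOSE	X
AMP	AMP	X
ATP	ATP	X
CDP-1,2-dipalmitoylglycerol	CPD-12815
CTP	CTP
GMP	GMP	X
GTP	GTP	X
H+	PROTON	X
H2O	WATER	X
L-alanine	L-ALPHA-ALANINE
L-arginine	ARG
L-asparagine	ASN
L-aspartate	L-ASPARTATE
L-cysteine	CYS
L-glutamate	GLT
L-glutamine	GLN
L-histidine	HIS
L-isoleucine	ILE
L-leucine	LEU
L-lysine	LYS
L-methionine	MET
L-phenylalanine	PHE
L-proline	PRO
L-serine	SER
L-threonine	THR
L-tryptophan	TRP
L-tyrosine	TYR
L-valine	VAL
NAD+	NAD	X
NADH	NADH	X
NADP+	NADP	X
NADPH	NADPH	X
S-adenosyl-L-methionine	S-ADENOSYLMETHIONINE	X
UDP-N-acetyl-alpha-D-glucosamine	UDP-N-ACETYL-D-GLUCOSAMINE
C1	C1
UTP	UTP
chorismate	CHORISMATE	X
dATP	DATP
dCTP	DCTP
dGTP	DGTP
dTTP	TTP
di-trans,octa-cis-undecaprenyl diphosphate	UNDECAPRENYL-DIPHOSPHATE
dipalmitoyl phosphatidate	CPD0-1422
C6	C6
glycine	GLY
isopentenyl diphosphate	DELTA3-ISOPENTENYL-PP
phosphate	Pi	X
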