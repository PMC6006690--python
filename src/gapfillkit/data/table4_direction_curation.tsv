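biocyc_id	metabolic_goal	curated_direction
METHENYLTHFCYCLOHYDRO-RXN	Glycine and one-carbon metabolism	REVERSIBLE
HYPOXANPRIBOSYLTRAN-RXN	Histidine synthesis	PHYSIOL-R2L
IMP-DEHYDROG-RXN	Xanthine synthesis	REVERSIBLE
RIBOKIN-RXN	Ribose synthesis	PHYSIOL-L2R
RXN-14223	Ribose degradation	PHYSIOL-L2R
TYROSINE-AMINOTRANSFERASE-RXN	Tyrosine synthesis	REVERSIBLE
GLYC3PDEHYDROGBIOSYN-RXN	Phospholipid synthesis	PHYSIOL-R2L
1.1.1.8-RXN	Phospholipid synthesis	PHYSIOL-R2L
MALONYL-COA-ACP-TRANSACYL-RXN	Phospholipid synthesis	PHYSIOL-L2R
3-OXOACYL-ACP-REDUCT-RXN	Phospholipid synthesis	PHYSIOL-R2L
RXN0-6705	Phospholipid synthesis	PHYSIOL-R2L
PHOSPHAGLYPSYN-RXN	Phospholipid synthesis	PHYSIOL-L2R
H2PTERIDINEPYROPHOSPHOKIN-RXN	THF synthesis	PHYSIOL-L2R
RXN-9772	NAD synthesis	PHYSIOL-L2R
RIBULP3EPIM-RXN	Pentose phosphate pathway	REVERSIBLE
RIB5PISOM-RXN	Pentose phosphate pathway	REVERSIBLE
1TRANSKETO-RXN	Pentose phosphate pathway	REVERSIBLE
2TRANSKETO-RXN	Pentose phosphate pathway	REVERSIBLE
TRANSALDOL-RXN	Pentose phosphate pathway	REVERSIBLE
PHOSACETYLTRANS-RXN	Central carbon metabolism	REVERSIBLE
RXN-12195	Phosphorylation debugging	PHYSIOL-L2R
RXN-12196	Phosphorylation debugging	PHYSIOL-L2R
XANPRIBOSYLTRAN-RXN	Phosphorylation debugging	PHYSIOL-R2L
DCTP-PYROPHOSPHATASE-RXN	Phosphorylation debugging	PHYSIOL-L2R
RXN-7913	Phosphorylation debugging	PHYSIOL-L2R
ATPASE-RXN	Phosphorylation debugging	PHYSIOL-L2R
RXN0-5468	Phosphorylation debugging	PHYSIOL-L2R
ALDHDEHYDROG-RXN	Phosphorylation debugging	PHYSIOL-L2R
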