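# Curated reference list of known colloidal aggregators (SMILES<TAB>name).
# Small fixture list for the similarity arm of the aggregator screen; a full
# reference collection can be supplied via config instead.
Clc1ccccc1C(c1ccccc1)(c1ccccc1)n1ccnc1	clotrimazole
Clc1ccc(COC(Cn2ccnc2)c2ccc(Cl)cc2Cl)c(Cl)c1	miconazole
Clc1ccc(COC(Cn2ccnc2)c2ccc(Cl)cc2Cl)cc1	econazole
C(n1ccnc1)(c1ccccc1)c1ccc(-c2ccccc2)cc1	bifonazole
COc1cc(/C=C/C(=O)CC(=O)/C=C/c2ccc(O)c(OC)c2)ccc1O	curcumin
O=c1c(O)c(-c2ccc(O)c(O)c2)oc2cc(O)cc(O)c12	quercetin
CCc1oc2ccccc2c1C(=O)c1cc(Br)c(O)c(Br)c1	benzbromarone
CC/C(=C(\c1ccccc1)c1ccc(OCCN(C)C)cc1)c1ccccc1	tamoxifen
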