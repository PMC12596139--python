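gene	drug	interaction_type	source
BRAF	Vemurafenib	inhibitor	synthetic
BRAF	Dabrafenib	inhibitor	synthetic
EGFR	Erlotinib	inhibitor	synthetic
EGFR	Gefitinib	inhibitor	synthetic
EGFR	Osimertinib	inhibitor	synthetic
KRAS	Sotorasib	inhibitor	synthetic
KRAS	Adagrasib	inhibitor	synthetic
TP53	APR-246	reactivator	synthetic
MYC	Omomyc-mimetic	inhibitor	synthetic
CDKN2A	Palbociclib	pathway	synthetic
CDK4	Palbociclib	inhibitor	synthetic
CDK6	Ribociclib	inhibitor	synthetic
ERBB2	Trastuzumab	antibody	synthetic
ERBB2	Lapatinib	inhibitor	synthetic
ALK	Crizotinib	inhibitor	synthetic
ALK	Alectinib	inhibitor	synthetic
PIK3CA	Alpelisib	inhibitor	synthetic
BRCA1	Olaparib	PARP-synthetic-lethal	synthetic
BRCA2	Olaparib	PARP-synthetic-lethal	synthetic
FLT3	Midostaurin	inhibitor	synthetic
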