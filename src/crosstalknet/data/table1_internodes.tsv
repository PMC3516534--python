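gene	total_links	total_evid	links_insulin	evid_insulin	links_mito	evid_mito	partners_insulin	partners_mito
ABL1	12	21	10	18	2	3	YWHAH|CBL|SRC|CRK|BCR|PTK2|CRKL|GRB2|CSK|NCK1	WASF1|TP53
ALDOA	6	8	2	4	4	4	FBP1|FBP2	ALDH1B1|ALDH1A3|ALDH2|GPD2
ALDOB	5	7	2	4	3	3	FBP1|FBP2	ALDH1A3|ALDH1B1|ALDH2
ALDOC	5	7	2	4	3	3	FBP2|FBP1	ALDH1B1|ALDH1A3|ALDH2
DHX9	5	6	2	3	3	3	NOLC1|RPS6	BRCA1|SLC25A5|TUFM
HNRNPU	6	6	3	3	3	3	NOLC1|YWHAQ|RPS6	C1QBP|SLC25A5|TUFM
HSP90AA1	13	16	9	11	4	5	CALM1|YWHAG|YWHAH|IKBKB|SRC|YWHAB|PDPK1|YWHAQ|AKT1	TP53|TOMM34|TOMM70A|HSPD1
ILF3	6	6	3	3	3	3	NOLC1|RPS6|YWHAQ	SLC25A5|C1QBP|TUFM
MYBBP1A	6	8	3	4	3	4	PKLR|RPS6|NOLC1	POLG|SLC25A5|TUFM
NCL	7	10	4	6	3	4	RPS6|PRKCZ|PPARGC1A|NOLC1	TUFM|TP53|SLC25A5
NFKB1	7	9	4	6	3	3	IKBKB|SOCS3|MAP3K1|AKT2	BCL2L1|BCL2|MTIF2
NFKBIA	5	8	3	5	2	3	SRC|CAPN1|IKBKB	TP53|SLC25A5
NOS1	8	9	3	3	5	6	HRAS|PRKACA|CALML3	SLC25A15|SLC25A2|OTC|ASS1|PRKCA
NOS3	6	8	2	3	4	5	CAV1|AKT1	SLC25A2|ASS1|SLC25A15|OTC
NPM1	6	7	3	3	3	4	RPS6|GRB2|NOLC1	TUFM|SLC25A5|TP53
PKM2	4	6	1	3	3	3	PKLR	POLG|AK3L1|AK2
PRNP	6	7	3	4	3	3	CAV1|MAP2K1|GRB2	HSPD1|BAX|SOD1
RB1	8	9	3	3	5	6	INS|MAPK1|PIK3R3	C1QBP|BRCA1|TGM2|PHB|TRAP1
RELA	7	10	4	7	3	3	IKBKB|CALM1|IKBKB|PRKCZ	ETHE1|MTIF2|ESR1
RPL10	5	6	2	3	3	3	RPS6|NOLC1	PRKCA|SLC25A5|TUFM
RPL11	4	6	2	3	2	3	RPS6|NOLC1	SLC25A5|TUFM
RPL30	5	6	2	3	3	3	RPS6|NOLC1	TUFM|SLC25A5|MRPS15
RPL35A	5	6	2	3	3	3	NOLC1|RPS6	SLC25A5|TUFM|MPG
RPS14	4	6	2	3	2	3	RPS6|NOLC1	TUFM|SLC25A5
RPS9	5	6	2	3	3	3	NOLC1|RPS6	TUFM|SLC25A5|TOMM40
SNRPD1	7	7	4	4	3	3	EIF4E|PPP1CA|YWHAB|YWHAQ	C1QBP|HSPD1|TRAP1
TOP1	5	6	2	3	3	3	RPS6|NOLC1	TUFM|SLC25A5|TP53
TRAF2	6	9	4	6	2	3	MAP3K1|CAV1|MAPK10|MTOR	CASP8|MAP3K5
TRAF6	9	12	5	7	4	5	PRKCZ|SRC|MAP3K1|MAPK10|MAP2K1	NDUFA1|MT-CO2|HADHA|NDUFAF1
U2AF1	6	7	2	3	4	4	NOLC1|RPS6	SLC25A5|TRAP1|TUFM|HSPD1
YBX1	6	8	3	3	3	5	RPS6|NOLC1|AKT1	SLC25A5|TUFM|TP53
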