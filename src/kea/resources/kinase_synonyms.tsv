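raw	canonical
CK2A1	CSNK2A1
CK2A2	CSNK2A2
CK2ALPHA	CSNK2A1
CK1A	CSNK1A1
CK1D	CSNK1D
CK1E	CSNK1E
PKACA	PRKACA
PKACB	PRKACB
PKA	PRKACA
PKCA	PRKCA
PKCB	PRKCB
PKCD	PRKCD
PKCE	PRKCE
PKCZ	PRKCZ
PKCT	PRKCQ
PKCI	PRKCI
MEK1	MAP2K1
MEK2	MAP2K2
MKK3	MAP2K3
MKK4	MAP2K4
MKK6	MAP2K6
MKK7	MAP2K7
ERK1	MAPK3
ERK2	MAPK1
ERK5	MAPK7
JNK1	MAPK8
JNK2	MAPK9
JNK3	MAPK10
P38A	MAPK14
P38B	MAPK11
P38G	MAPK12
P38D	MAPK13
AKT1(PKB)	AKT1
PKB	AKT1
PKBBETA	AKT2
PKBGAMMA	AKT3
S6K1	RPS6KB1
S6K2	RPS6KB2
P70S6K	RPS6KB1
RSK1	RPS6KA1
RSK2	RPS6KA3
RSK3	RPS6KA2
RSK4	RPS6KA6
MSK1	RPS6KA5
MSK2	RPS6KA4
CDC2	CDK1
AURORA-A	AURKA
AURORA-B	AURKB
AURORA-C	AURKC
AURA	AURKA
AURB	AURKB
PDK1(PDPK1)	PDPK1
PDK1	PDPK1
CHK1	CHEK1
CHK2	CHEK2
GSK3ALPHA	GSK3A
GSK3BETA	GSK3B
CAMK2	CAMK2A
CAMKII-ALPHA	CAMK2A
DNAPK	PRKDC
DNA-PK	PRKDC
MTOR(FRAP1)	MTOR
FRAP1	MTOR
ABL	ABL1
SRC-FAMILY	SRC
FYN-ISOFORM1	FYN
ZAP70	ZAP70
PLK	PLK1
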