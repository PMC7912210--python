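raw	canonical
PADI4	PADI4
CEACAM6	CEACAM6
SLC26A4	SLC26A4
MMP3	MMP3
LGSN	LGSN
C20orf85	C20orf85
DMRTC2	DMRTC2
EVPLL	EVPLL
TAS1R2	TAS1R2
HYAL3	HYAL3
TBCC	TBCC
VTCN1	VTCN1
X4.SEP	SEPT4
DISC1	DISC1
TDRD9	TDRD9
THBS2	THBS2
CHRM4	CHRM4
CCDC151	CCDC151
ALPP	ALPP
INSC	INSC
GPR45	GPR45
PCDHB5	PCDHB5
ITGA2B	ITGA2B
PLOD1	PLOD1
SLC30A3	SLC30A3
PRKAR2B	PRKAR2B
TMEM53	TMEM53
PCDHB12	PCDHB12
GUCY2D	GUCY2D
TCTE3	TCTE3
CEACAM4	CEACAM4
TNFSF13	TNFSF13
CNTNAP3	CNTNAP3
LRRC4C	LRRC4C
SEC14L4	SEC14L4
DHRS7C	DHRS7C
SLC26A9	SLC26A9
OLIG1	OLIG1
GRINA	GRINA
PVRL2	PVRL2
TENC1	TENC1
NEU4	NEU4
SIPA1L2	SIPA1L2
SPARC	SPARC
TREML1	TREML1
GBAP1	GBAP1
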