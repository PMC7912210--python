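raw	canonical
PRPH	PRPH
POU6F2	POU6F2
CNR2	CNR2
SALL4	SALL4
CNTD1	CNTD1
TPO	TPO
GLDC	GLDC
KLHDC9	KLHDC9
KCNA7	KCNA7
SYNJ2BP	SYNJ2BP
MMP20	MMP20
PRR7	PRR7
ROR2	ROR2
LRRC66	LRRC66
SYN3	SYN3
ULBP1	ULBP1
PLCZ1	PLCZ1
CATSPERB	CATSPERB
ZNF165	ZNF165
P2RX4	P2RX4
GIMAP7	GIMAP7
NKX3.2	NKX3-2
CSNK2A1	CSNK2A1
LIG1	LIG1
C10orf95	C10orf95
HOXD11	HOXD11
MRPL13	MRPL13
BRDT	BRDT
SYTL2	SYTL2
RBM20	RBM20
SPARCL1	SPARCL1
ZNF514	ZNF514
GRHL2	GRHL2
SLC18A1	SLC18A1
GNMT	GNMT
LRRC3B	LRRC3B
GZMA	GZMA
FAM118A	FAM118A
TDRD12	TDRD12
RPLP0	RPLP0
CXCL13	CXCL13
CCDC33	CCDC33
ZNF257	ZNF257
C1orf204	C1orf204
BOLA3	BOLA3
TSSK3	TSSK3
KANK3	KANK3
ENPP3	ENPP3
GSTA4	GSTA4
AKR1C3	AKR1C3
KLHDC4	KLHDC4
EXTL2	EXTL2
SIRT4	SIRT4
FGF9	FGF9
SCG5	SCG5
FUT8	FUT8
OOEP	OOEP
TNIP3	TNIP3
PDPR	PDPR
PLEKHA1	PLEKHA1
SOX7	SOX7
C16orf52	C16orf52
RASGEF1B	RASGEF1B
WDR63	WDR63
TBX21	TBX21
HLA.DQA2	HLA-DQA2
KLF2	KLF2
LTV1	LTV1
QRSL1	QRSL1
XCL1	XCL1
YLPM1	YLPM1
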