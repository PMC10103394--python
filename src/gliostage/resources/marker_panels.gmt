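PRE_OPC	canonical cell-type marker panel	ASCL1	BTG2	HES6	DLL1	DLL3
OPC	canonical cell-type marker panel	PDGFRA	CSPG4	PCDH15	PTPRZ1
COP	canonical cell-type marker panel	NEU4	SOX6	VCAN
ASTROCYTE	canonical cell-type marker panel	ALDOC	AQP4	CLU	GFAP	MLC1	S100B	GLT1
APC	canonical cell-type marker panel	FABP7	FGFR3	GLAST
OLIGODENDROCYTE	canonical cell-type marker panel	MOBP	MBP	MOG	KLK6
T_CELL	canonical cell-type marker panel	CD2	CD3D	CD3E	CD3G
MICROGLIA	canonical cell-type marker panel	CX3CR1	P2RY12	TMEM119
MACROPHAGE	canonical cell-type marker panel	CD163	S100A8	S100A9	AIF1
PROLIFERATION	canonical cell-type marker panel	MKI67	TOP2A	CCNB2	CDK1
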