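MYELINATION	myelin components and myelination regulators	GALC	MAG	MBP	MOBP	MOG	MYRF	SOX10	PLP1	CNP
OPC_REGULATORS	regulators of OPC specification and maintenance	MYT1	OLIG2	PDGFRA	PTPRZ1	SMOC1	SOX8
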