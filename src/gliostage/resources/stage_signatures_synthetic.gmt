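OPC	synthetic default stage signature (anchor markers + SYN* filler)	PDGFRA	CSPG4	PCDH15	PTPRZ1	OLIG1	LHFPL3	SYNOPC01	SYNOPC02	SYNOPC03	SYNOPC04	SYNOPC05	SYNOPC06	SYNOPC07	SYNOPC08	SYNOPC09	SYNOPC10	SYNOPC11	SYNOPC12	SYNOPC13	SYNOPC14	SYNOPC15	SYNOPC16	SYNOPC17	SYNOPC18	SYNOPC19	SYNOPC20	SYNOPC21	SYNOPC22	SYNOPC23	SYNOPC24
COP	synthetic default stage signature (anchor markers + SYN* filler)	NEU4	SOX6	VCAN	GPR17	BMP4	SYNCOP01	SYNCOP02	SYNCOP03	SYNCOP04	SYNCOP05	SYNCOP06	SYNCOP07	SYNCOP08	SYNCOP09	SYNCOP10	SYNCOP11	SYNCOP12	SYNCOP13	SYNCOP14	SYNCOP15	SYNCOP16	SYNCOP17	SYNCOP18	SYNCOP19	SYNCOP20	SYNCOP21	SYNCOP22	SYNCOP23	SYNCOP24	SYNCOP25
NFOL	synthetic default stage signature (anchor markers + SYN* filler)	TCF7L2	ENPP6	NKX2-2	ITPR2	SYNNFOL01	SYNNFOL02	SYNNFOL03	SYNNFOL04	SYNNFOL05	SYNNFOL06	SYNNFOL07	SYNNFOL08	SYNNFOL09	SYNNFOL10	SYNNFOL11	SYNNFOL12	SYNNFOL13	SYNNFOL14	SYNNFOL15	SYNNFOL16	SYNNFOL17	SYNNFOL18	SYNNFOL19	SYNNFOL20	SYNNFOL21	SYNNFOL22	SYNNFOL23	SYNNFOL24	SYNNFOL25	SYNNFOL26
MFOL	synthetic default stage signature (anchor markers + SYN* filler)	MAL	OPALIN	CTPS1	SERINC5	SYNMFOL01	SYNMFOL02	SYNMFOL03	SYNMFOL04	SYNMFOL05	SYNMFOL06	SYNMFOL07	SYNMFOL08	SYNMFOL09	SYNMFOL10	SYNMFOL11	SYNMFOL12	SYNMFOL13	SYNMFOL14	SYNMFOL15	SYNMFOL16	SYNMFOL17	SYNMFOL18	SYNMFOL19	SYNMFOL20	SYNMFOL21	SYNMFOL22	SYNMFOL23	SYNMFOL24	SYNMFOL25	SYNMFOL26
MO	synthetic default stage signature (anchor markers + SYN* filler)	GALC	KLK6	APOD	TRF	PMP22	SYNMO01	SYNMO02	SYNMO03	SYNMO04	SYNMO05	SYNMO06	SYNMO07	SYNMO08	SYNMO09	SYNMO10	SYNMO11	SYNMO12	SYNMO13	SYNMO14	SYNMO15	SYNMO16	SYNMO17	SYNMO18	SYNMO19	SYNMO20	SYNMO21	SYNMO22	SYNMO23	SYNMO24	SYNMO25
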