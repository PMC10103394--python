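EM	synthetic default EGFR-module signature	EGFR	NES	CD44	CHI3L1	VIM	SYNEM01	SYNEM02	SYNEM03	SYNEM04	SYNEM05	SYNEM06	SYNEM07	SYNEM08	SYNEM09	SYNEM10	SYNEM11	SYNEM12	SYNEM13	SYNEM14	SYNEM15	SYNEM16	SYNEM17	SYNEM18	SYNEM19	SYNEM20	SYNEM21	SYNEM22	SYNEM23	SYNEM24	SYNEM25
PM	synthetic default PDGFRA-module signature	OLIG2	SOX4	DLL3	SOX8	CCND2	SYNPM01	SYNPM02	SYNPM03	SYNPM04	SYNPM05	SYNPM06	SYNPM07	SYNPM08	SYNPM09	SYNPM10	SYNPM11	SYNPM12	SYNPM13	SYNPM14	SYNPM15	SYNPM16	SYNPM17	SYNPM18	SYNPM19	SYNPM20	SYNPM21	SYNPM22	SYNPM23	SYNPM24	SYNPM25
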