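ABCC8
ACTL6B
ADPRHL2
AK2
AKIRIN1
ALDH1L2
ANO5
ATCAY
ATOH8
CACNG2
CAP1
CAPNS1
CAPZA1
CAPZB
CARD8
CCDC23
CCNL2
CDC42
CDHR1
CHGB
CLVS1
CMBL
CMPK1
CRTAC1
CSDE1
CYB561D1
DDX20
DNAJC8
DOCK7
DR1
EID2
ERCC1
EXOSC10
EXTL2
EYA3
FAM155A
FBXO42
FKRP
FNBP1L
FOXJ3
FPGT
GABRB3
GDAP1L1
GFRA1
GNAI3
GNB1
GNG12
GNG5
GPBP1L1
GRIN3A
HDAC1
HEXIM2
HIP1R
HMGCL
HP1BP3
HSPB11
IQGAP1
IRF3
KCNIP2
KCNK3
KDELR1
KIAA0355
KIAA2013
KPNA6
L1CAM
LRPPRC
LRRC41
LRRC8D
LRRTM4
LSM10
LSM14A
MCPH1
MEAF6
MFN2
MIER1
MMAB
MRPS15
MTF1
MTF2
NADK
NDUFA3
NECAP2
NOG
NRAS
NRD1
NUDT7
PDE8A
PEF1
PHACTR4
PHF13
PKN2
PLEKHM2
POMGNT1
PPCS
PPP1R8
PRPF31
PTP4A2
RABAC1
RAP1A
RER1
REST
RPF1
RPL22L1
S100PBP
SCAMP1
SCMH1
SCP2
SDF4
SEZ6L
SEZ6L2
SH3GLB1
SHISA9
SLC30A7
SLC8A3
SPR
SRRM1
SRSF11
SRSF4
SSU72
STK40
SVOP
TCEB3
TMEM167B
TRAPPC3
TRIM67
TRIT1
TXNDC12
UBA2
UROD
WASF2
YTHDF2
ZBTB8OS
ZCCHC11
ZCCHC17
ZDHHC22
ZNF45
ZNF518B
ZZZ3
C1orf144
C1orf151
C1orf175
C2orf67
FAM123C
FAM54B
HBXIP
KIAA0485
KIAA1409
PNRC2
LOC257396
LOC283484
MYH6
NCRNA00219
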