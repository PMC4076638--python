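gene,role,status
BIRC5,target,reported
BIRC3,target,reported
TNF,target,reported
BIRC2,target,placeholder
XIAP,target,placeholder
NAIP,target,placeholder
BIRC7,target,placeholder
CASP1,target,placeholder
CASP2,target,placeholder
CASP3,target,placeholder
CASP4,target,placeholder
CASP5,target,placeholder
CASP6,target,placeholder
CASP7,target,placeholder
CASP8,target,placeholder
CASP9,target,placeholder
CASP10,target,placeholder
CASP14,target,placeholder
BCL2,target,placeholder
BCL2L1,target,placeholder
BCL2L2,target,placeholder
BCL2L10,target,placeholder
BCL2L11,target,placeholder
BCL2A1,target,placeholder
MCL1,target,placeholder
BAX,target,placeholder
BAK1,target,placeholder
BID,target,placeholder
BAD,target,placeholder
BIK,target,placeholder
BOK,target,placeholder
HRK,target,placeholder
PMAIP1,target,placeholder
BBC3,target,placeholder
BNIP3,target,placeholder
BNIP3L,target,placeholder
BCL10,target,placeholder
BCLAF1,target,placeholder
TP53,target,placeholder
TP73,target,placeholder
TP53BP2,target,placeholder
TP53I3,target,placeholder
CDKN1A,target,placeholder
MDM2,target,placeholder
GADD45A,target,placeholder
FAS,target,placeholder
FASLG,target,placeholder
FADD,target,placeholder
TRADD,target,placeholder
TNFRSF1A,target,placeholder
TNFRSF1B,target,placeholder
TNFRSF10A,target,placeholder
TNFRSF10B,target,placeholder
TNFRSF21,target,placeholder
TNFRSF25,target,placeholder
TNFSF10,target,placeholder
LTA,target,placeholder
LTBR,target,placeholder
CD40,target,placeholder
CD40LG,target,placeholder
CD27,target,placeholder
CD70,target,placeholder
RIPK1,target,placeholder
RIPK2,target,placeholder
CFLAR,target,placeholder
APAF1,target,placeholder
CYCS,target,placeholder
DIABLO,target,placeholder
HTRA2,target,placeholder
AIFM1,target,placeholder
ENDOG,target,placeholder
DFFA,target,placeholder
DFFB,target,placeholder
GZMB,target,placeholder
PRF1,target,placeholder
NFKB1,target,placeholder
RELA,target,placeholder
AKT1,target,placeholder
MAPK8,target,placeholder
JUN,target,placeholder
MYC,target,placeholder
NOL3,target,placeholder
CARD8,target,placeholder
NLRP1,target,placeholder
PYCARD,target,placeholder
CRADD,target,placeholder
DAPK1,target,placeholder
ABL1,target,placeholder
TRAF2,target,placeholder
TRAF3,target,placeholder
CASP8AP2,target,placeholder
CIDEA,target,placeholder
ACTB,reference,reported
TBP,reference,reported
HMBS,reference,reported
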