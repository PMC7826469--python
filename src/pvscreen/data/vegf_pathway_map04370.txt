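# VEGF signaling pathway gene set (KEGG map04370 members), shipped as a
# static list so no live database access is ever needed.
VEGFA
KDR
SHC2
PLCG1
PLCG2
SPHK1
SPHK2
SPHKAP
PRKCA
PRKCB
PRKCG
PTGS2
PLA2G4A
NOS3
SRC
PXN
PTK2
CDC42
MAPK11
MAPK12
MAPK13
MAPK14
MAPKAPK2
MAPKAPK3
HSPB1
PIK3CA
PIK3CB
PIK3CD
PIK3R1
PIK3R2
AKT1
AKT2
AKT3
BAD
CASP9
RAC1
RAC2
RAC3
HRAS
KRAS
NRAS
RAF1
MAP2K1
MAP2K2
MAPK1
MAPK3
PPP3CA
PPP3CB
PPP3CC
NFATC2
NFATC4
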