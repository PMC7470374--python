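# Gene panel definitions for the three multigene assays.
#
# Provenance: the assay publications themselves (Paik et al. 2004 for the
# Oncotype DX panel; Parker et al. 2009 and patent US20130337444A1 for the
# Prosigna/PAM50 panel; van 't Veer 2002 / van de Vijver 2002 for MammaPrint).
# The Oncotype panel, its role partition and its five reference genes, the
# Prosigna eight housekeeping genes and the PAM50 gene list are taken from the
# published literature. The exact 46-gene Prosigna subset of PAM50, its
# 18-gene proliferation subset, and the 70-gene MammaPrint list could not be
# verified against the primary sources when this file was assembled and are
# plausible RECONSTRUCTIONS (synthetic stand-ins with the documented
# structure: 46 reporters of which 18 proliferation; 70 reporters), suitable
# for closed-loop simulation studies but not for scoring clinical data.
prosigna:
  housekeeping: [ACTB, GAPDH, GUSB, MRPL19, PSMC4, PUM1, RPLP0, SF3A1]
  reporters:
    ACTR3B: basal
    ANLN: proliferation
    BAG1: luminal
    BCL2: luminal
    BIRC5: proliferation
    CCNB1: proliferation
    CCNE1: proliferation
    CDC20: proliferation
    CDC6: proliferation
    CDH3: basal
    CENPF: other
    CEP55: proliferation
    CXXC5: luminal
    EGFR: basal
    ERBB2: her2
    ESR1: luminal
    EXO1: proliferation
    FGFR4: her2
    FOXA1: luminal
    FOXC1: basal
    GRB7: her2
    KIF2C: proliferation
    KRT14: basal
    KRT17: basal
    KRT5: basal
    MAPT: luminal
    MELK: proliferation
    MIA: basal
    MKI67: proliferation
    MLPH: luminal
    MMP11: other
    MYBL2: other
    MYC: other
    NAT1: luminal
    NDC80: proliferation
    NUF2: proliferation
    ORC6: proliferation
    PGR: luminal
    PHGDH: basal
    PTTG1: proliferation
    RRM2: proliferation
    SFRP1: basal
    SLC39A6: luminal
    TYMS: proliferation
    UBE2C: proliferation
    UBE2T: other
oncotype:
  housekeeping: [ACTB, GAPDH, GUSB, RPLP0, TFRC]
  reporters:
    MKI67: proliferation
    AURKA: proliferation
    BIRC5: proliferation
    CCNB1: proliferation
    MYBL2: proliferation
    GRB7: her2
    ERBB2: her2
    ESR1: er
    PGR: er
    BCL2: er
    SCUBE2: er
    MMP11: invasion
    CTSV: invasion
    CD68: singleton
    GSTM1: singleton
    BAG1: singleton
mammaprint:
  housekeeping: []
  reporters:
    ALDH4A1: metabolism
    BBC3: apoptosis
    CDCA7: proliferation
    CDKN3: proliferation
    CENPA: proliferation
    CKS2: proliferation
    COL4A2: ecm
    DCK: metabolism
    DHX58: other
    DIAPH3: invasion
    DTL: proliferation
    EBF4: other
    ECI2: metabolism
    ECT2: proliferation
    EGLN1: hypoxia
    ESM1: angiogenesis
    ESPL1: proliferation
    EXT1: other
    FGF18: signalling
    FLT1: angiogenesis
    GMPS: metabolism
    GNAZ: signalling
    GPR126: signalling
    GPR180: signalling
    GSTM3: metabolism
    HRASLS: signalling
    IGFBP5: signalling
    KDM7A: other
    KIF23: proliferation
    LPCAT1: metabolism
    MCM2: proliferation
    MCM6: proliferation
    MMP9: invasion
    MS4A7: immune
    MTDH: other
    NDUFS7: metabolism
    NMU: signalling
    NUSAP1: proliferation
    ORC1: proliferation
    OXCT1: metabolism
    PALM2: other
    PEX12: other
    PITRM1: other
    PLAAT1: other
    PRC1: proliferation
    QSOX2: other
    RAB6B: other
    RASSF7: signalling
    RECQL5: other
    RFC4: proliferation
    RTN4RL1: other
    RUNDC1: other
    SERF1A: other
    SLC2A3: metabolism
    STK32B: signalling
    TGFB3: signalling
    TMEM74B: other
    TSPYL5: other
    TTK: proliferation
    UCHL5: other
    WISP1: ecm
    ZNF385B: other
    ZNF533: other
    AKAP2: other
    AP2B1: other
    AYTL2: other
    C16orf61: other
    C9orf30: other
    CCDC74A: other
    LOC100131053: other
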