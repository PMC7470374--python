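# Synthetic stand-in for the MammaPrint good-prognosis average profile
# (van 't Veer 2002 / van de Vijver 2002). The 0.4 correlation cutoff is
# the published value; the per-gene template values are synthetic.
# correlation_cutoff	0.4
gene	template
ALDH4A1	0.7829
BBC3	0.4477
CDCA7	-0.4611
CDKN3	-0.1202
CENPA	0.5292
CKS2	-0.5472
COL4A2	-0.1416
DCK	-0.4160
DHX58	0.3343
DIAPH3	0.0941
DTL	-0.2957
EBF4	0.3361
ECI2	-0.4442
ECT2	-0.0714
EGLN1	0.4832
ESM1	-0.9521
ESPL1	0.6011
EXT1	0.4466
FGF18	0.1978
FLT1	-1.1470
GMPS	0.5494
GNAZ	0.2206
GPR126	-0.3597
GPR180	0.0293
GSTM3	-0.6369
HRASLS	-0.1507
IGFBP5	-0.1630
KDM7A	0.6302
KIF23	-0.5894
LPCAT1	-0.6133
MCM2	-0.2849
MCM6	0.6049
MMP9	0.0579
MS4A7	-0.1502
MTDH	0.3966
NDUFS7	0.4105
NMU	-0.0237
NUSAP1	1.0102
ORC1	-0.3762
OXCT1	0.2280
PALM2	0.3185
PEX12	-0.2496
PITRM1	0.2016
PLAAT1	-0.1953
PRC1	0.1602
QSOX2	-0.2404
RAB6B	0.6650
RASSF7	0.2679
RECQL5	0.3903
RFC4	-0.7430
RTN4RL1	-1.4574
RUNDC1	-0.4877
SERF1A	0.4477
SLC2A3	-0.2187
STK32B	-0.0562
TGFB3	0.8901
TMEM74B	-0.7648
TSPYL5	0.3374
TTK	0.0404
UCHL5	-0.1350
WISP1	-0.4499
ZNF385B	-0.7503
ZNF533	0.6407
AKAP2	-0.3634
AP2B1	0.1678
AYTL2	-0.0265
C16orf61	-0.2610
C9orf30	-0.4276
CCDC74A	0.2521
LOC100131053	1.6012
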