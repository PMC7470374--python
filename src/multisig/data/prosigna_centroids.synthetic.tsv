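# Synthetic stand-in for the published Prosigna/PAM50 subtype centroids
# (Parker et al. 2009 / patent US20130337444A1). Role-structured values
# on the row-scaled scale; NOT the proprietary centroid values.
gene	LumA	LumB	Her2	Basal
ACTR3B	-0.6374	-0.9265	-0.1927	0.8494
ANLN	-0.9194	0.5657	0.5441	0.7766
BAG1	1.0056	0.2716	-0.4376	-0.8577
BCL2	0.8830	0.8567	-0.2562	-1.1000
BIRC5	-1.5548	0.3370	0.5172	0.9866
CCNB1	-1.1525	0.6141	0.6183	0.4207
CCNE1	-0.6823	0.6781	0.3018	1.1358
CDC20	-1.2084	0.8822	0.7742	0.8886
CDC6	-0.9180	1.1088	0.6306	0.8789
CDH3	-0.7500	-0.8018	0.1973	1.6599
CENPF	-0.1048	0.1080	0.0402	0.1743
CEP55	-1.0999	0.6820	0.6014	0.7326
CXXC5	0.8246	0.6078	-0.5462	-0.9937
EGFR	-0.4732	-0.3980	0.1039	0.7325
ERBB2	-0.4948	-0.0200	1.2133	-0.5031
ESR1	1.1561	0.3855	-0.8291	-0.5889
EXO1	-1.0109	0.1537	0.7096	1.1845
FGFR4	-0.4172	-0.1355	0.8290	-0.3724
FOXA1	1.1449	0.7759	-0.4683	-0.8596
FOXC1	-0.6284	-0.2840	0.1005	1.4268
GRB7	-0.0445	-0.1557	0.7169	-0.3273
KIF2C	-0.9173	0.9089	0.7583	0.8512
KRT14	-0.7465	-0.3221	-0.4978	1.0352
KRT17	-0.8955	-0.6324	-0.4178	1.5177
KRT5	-0.4606	-0.7250	-0.5595	1.0830
MAPT	1.2593	0.6013	-0.9965	-0.9196
MELK	-1.2434	0.9688	0.4021	0.6684
MIA	-1.0321	-0.4724	-0.4296	1.3833
MKI67	-0.9636	0.9423	0.4071	0.6357
MLPH	0.8449	0.2902	-0.3714	-0.8961
MMP11	-0.2888	0.0756	0.2519	-0.0013
MYBL2	-0.0145	0.4334	-0.0872	0.1578
MYC	-0.0309	0.3823	-0.0990	0.1457
NAT1	1.2161	0.7469	-0.7241	-0.8638
NDC80	-0.8769	0.5018	0.3835	0.9577
NUF2	-1.0232	0.6324	0.8667	0.9640
ORC6	-0.9730	0.6164	0.1925	0.9268
PGR	0.8230	0.5604	-0.1890	-0.7871
PHGDH	-0.6162	-0.3227	-0.2944	1.1922
PTTG1	-0.6538	0.3304	0.5252	0.5741
RRM2	-1.1505	0.3489	0.8159	1.1839
SFRP1	-0.5591	-0.0319	0.0258	0.9576
SLC39A6	1.0142	0.5466	-0.6033	-1.2217
TYMS	-0.9564	0.1318	0.8316	0.3857
UBE2C	-0.7861	0.5990	0.8661	1.1735
UBE2T	-0.2524	-0.2644	0.6333	0.2821
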