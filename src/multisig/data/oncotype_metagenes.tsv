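# Oncotype DX Recurrence Score metagene membership and per-gene averaging
# weights, from Paik et al. 2004 (NEJM 351:2817-26). Each metagene is the
# weighted average of its member genes: sum(w*x)/sum(w).
gene	metagene	weight
GRB7	her2	0.9
ERBB2	her2	0.1
ESR1	er	0.8
PGR	er	1.2
BCL2	er	1.0
SCUBE2	er	1.0
MKI67	proliferation	1.0
AURKA	proliferation	1.0
BIRC5	proliferation	1.0
CCNB1	proliferation	1.0
MYBL2	proliferation	1.0
MMP11	invasion	1.0
CTSV	invasion	1.0
CD68	cd68	1.0
GSTM1	gstm1	1.0
BAG1	bag1	1.0
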