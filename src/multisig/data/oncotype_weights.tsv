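# Oncotype DX unscaled Recurrence Score coefficients (Paik et al. 2004):
# RSu = 0.47*her2 - 0.34*er + 1.04*proliferation + 0.10*invasion
#       + 0.05*CD68 - 0.08*GSTM1 - 0.07*BAG1
# and the published mapping to the reported 0-100 scale RS = 20*(RSu - 6.7),
# i.e. offset -134, slope 20, truncated to [0, 100].
name	value
her2	0.47
er	-0.34
proliferation	1.04
invasion	0.10
cd68	0.05
gstm1	-0.08
bag1	-0.07
rs_rescale_offset	-134.0
rs_rescale_slope	20.0
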