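# Synthetic stand-in for the Prosigna ROR linear-combination weights and the
# final 0-100 rescale constants (patent US20130337444A1; the rescale constants
# are not publicly reported at all). Signs and magnitudes follow the published
# description (negative LumA, positive Basal/proliferation, small positive
# tumour-size term); the literal values are synthetic.
name	value
subtype_LumA	-0.60
subtype_LumB	0.35
subtype_Her2	0.50
subtype_Basal	0.85
proliferation	1.10
size	0.15
rescale_offset	52.0
rescale_slope	16.0
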