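# Explicit gene-symbol alias table (legacy symbol -> panel symbol).
# Matching is case-insensitive after trimming; no fuzzy matching.
alias	symbol
CTSL2	CTSV
STK15	AURKA
AURK-A	AURKA
KNTC2	NDC80
CDCA1	NUF2
ORC6L	ORC6
HER2	ERBB2
KI67	MKI67
GUS	GUSB
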