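# family	pattern	anchor
# Pattern language: literal residues, X = any residue, [AB] = alternatives,
# X(n) = n arbitrary residues, trailing "a" = peptide must be amidated.
# Priority = file order (first match wins).
ASTC	SXWKQCXFNAVSCFa	C-terminal
ASTB	WX(6)Wa	C-terminal
ASTA	[YF]XFG[LIV]a	C-terminal
SULF	[YF]G[HMF][MLF][RK]Fa	C-terminal
SIF	SIFa	C-terminal
TRP	FX(1)GX(1)Ra	C-terminal
NPF	RX(1)RFa	C-terminal
PDH	LPKIMNEAa	C-terminal
CALCI	GGPa	C-terminal
ORCO	NFDEIDR	N-terminal
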