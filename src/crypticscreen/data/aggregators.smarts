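polyphenol_catechol	c1cc(O)c(O)cc1
quinone	O=C1C=CC(=O)C=C1
rhodanine	O=C1CSC(=S)N1
long_alkyl_chain	[CH2][CH2][CH2][CH2][CH2][CH2][CH2][CH2]
fused_polyaromatic	c1ccc2c(c1)ccc3c2cccc3
curcumin_dienone	C(=O)C=Cc1ccccc1
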