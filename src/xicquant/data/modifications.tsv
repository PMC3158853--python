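# Built-in modification registry.  target is a set of residue letters, or
# "nt:X"/"ct:X" for a terminal modification restricted to residue X
# ("nt"/"ct" alone allow any terminal residue).  formula is a signed
# elemental delta, e.g. "H-3N-1" for loss of NH3.
name	target	formula
Carbamidomethyl	C	C2H3N1O1
Oxidation	M	O1
Phospho	STY	H1O3P1
Pyro-glu	nt:Q	H-3N-1
Pyro-glu-E	nt:E	H-2O-1
Acetyl	nt	C2H2O1
Deamidated	NQ	H-1N-1O1
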