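# Variable/fixed modification panel.  Deltas in Da.  v1
# Target tokens: residue letters; nterm (any N-terminal residue); nterm:X (N-terminal residue X only)
# name	delta_mono	delta_avg	targets	max_per_peptide
Deamidated	0.98402	0.9848	N;Q	2
Oxidation	15.99491	15.9994	M;W;P;Y	2
Dioxidation	31.98983	31.9988	P;W;Y;M	2
Trp->Kynurenine	3.99491	3.9884	W	1
Carbamidomethyl	57.02146	57.0513	C;K;nterm	2
Gln->pyro-Glu	-17.026549	-17.03052	nterm:Q	1
Glu->pyro-Glu	-18.010565	-18.01528	nterm:E	1
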