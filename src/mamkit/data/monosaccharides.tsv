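# Monosaccharide residue masses (Da), monoisotopic and average.  v1
# name	monoisotopic	average
Hex	162.05282	162.1406
HexNAc	203.07937	203.1925
dHex	146.05791	146.1412
NeuAc	291.09542	291.2546
NeuGc	307.09033	307.2540
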