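# Short names for common mAb N-glycan compositions.  v1
# short_name	hex	hexnac	dhex	neuac	neugc
G0	3	4	0	0	0
G0F	3	4	1	0	0
G1	4	4	0	0	0
G1F	4	4	1	0	0
G2	5	4	0	0	0
G2F	5	4	1	0	0
G0F-GlcNAc	3	3	1	0	0
G1F-GlcNAc	4	3	1	0	0
G0-GlcNAc	3	3	0	0	0
Man5	5	2	0	0	0
Man6	6	2	0	0	0
Man7	7	2	0	0	0
A1F	4	4	1	1	0
A2F	5	4	1	1	0
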