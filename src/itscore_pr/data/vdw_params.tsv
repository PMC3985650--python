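# Amber-style 6-12 parameters per atom type symbol (default set;
# users may supply their own file with the same columns)
symbol	radius	well_depth
C2+	1.908	0.086
C2-	1.908	0.086
C2M	1.908	0.086
C2S	1.908	0.086
Car	1.908	0.086
C2X	1.908	0.086
C3C	1.908	0.1094
C3A	1.908	0.1094
C3X	1.908	0.1094
N2N	1.824	0.17
N2+	1.824	0.17
N2X	1.824	0.17
Nar	1.824	0.17
N21	1.824	0.17
N3+	1.824	0.17
O2M	1.6612	0.21
O2S	1.6612	0.21
O2	1.6612	0.21
O2-	1.6612	0.21
O3H	1.721	0.2104
O31	1.721	0.2104
O32	1.721	0.2104
S31	2.0	0.25
S30	2.0	0.25
P	2.1	0.2
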