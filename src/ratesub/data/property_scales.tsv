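# Amino-acid side-chain property scales used to build the delta_V and delta_P
# conservativeness matrices.
# volume: side-chain volume in A^3 (Grantham 1974, Science 185:862, column c).
# polarity: side-chain polarity, dimensionless (Grantham 1974, column p;
#           originally Woese et al. polar requirement).
# Columns: one-letter code, volume, polarity. Tab-separated.
aa	volume	polarity
A	31	8.1
R	124	10.5
N	56	11.6
D	54	13.0
C	55	5.5
Q	85	10.5
E	83	12.3
G	3	9.0
H	96	10.4
I	111	5.2
L	111	4.9
K	119	11.3
M	105	5.7
F	132	5.2
P	32.5	8.0
S	32	9.2
T	61	8.6
W	170	5.4
Y	136	6.2
V	84	5.9
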