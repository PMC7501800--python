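# Synthetic stand-in for the normalized EX exchangeability matrix.
# Built by min-max normalizing canonical BLOSUM62 off-diagonal scores
# into [0,1] (diagonal set to 1). Symmetric; extrema 0 and 1 attained.
# NOT the published laboratory-mutagenesis EX values.
	A	R	N	D	C	Q	E	G	H	I	L	K	M	F	P	S	T	W	Y	V
A	1	0.428571	0.285714	0.285714	0.571429	0.428571	0.428571	0.571429	0.285714	0.428571	0.428571	0.428571	0.428571	0.285714	0.428571	0.714286	0.571429	0.142857	0.285714	0.571429
R	0.428571	1	0.571429	0.285714	0.142857	0.714286	0.571429	0.285714	0.571429	0.142857	0.285714	0.857143	0.428571	0.142857	0.285714	0.428571	0.428571	0.142857	0.285714	0.142857
N	0.285714	0.571429	1	0.714286	0.142857	0.571429	0.571429	0.571429	0.714286	0.142857	0.142857	0.571429	0.285714	0.142857	0.285714	0.714286	0.571429	0	0.285714	0.142857
D	0.285714	0.285714	0.714286	1	0.142857	0.571429	0.857143	0.428571	0.428571	0.142857	0	0.428571	0.142857	0.142857	0.428571	0.571429	0.428571	0	0.142857	0.142857
C	0.571429	0.142857	0.142857	0.142857	1	0.142857	0	0.142857	0.142857	0.428571	0.428571	0.142857	0.428571	0.285714	0.142857	0.428571	0.428571	0.285714	0.285714	0.428571
Q	0.428571	0.714286	0.571429	0.571429	0.142857	1	0.857143	0.285714	0.571429	0.142857	0.285714	0.714286	0.571429	0.142857	0.428571	0.571429	0.428571	0.285714	0.428571	0.285714
E	0.428571	0.571429	0.571429	0.857143	0	0.857143	1	0.285714	0.571429	0.142857	0.142857	0.714286	0.285714	0.142857	0.428571	0.571429	0.428571	0.142857	0.285714	0.285714
G	0.571429	0.285714	0.571429	0.428571	0.142857	0.285714	0.285714	1	0.285714	0	0	0.285714	0.142857	0.142857	0.285714	0.571429	0.285714	0.285714	0.142857	0.142857
H	0.285714	0.571429	0.714286	0.428571	0.142857	0.571429	0.571429	0.285714	1	0.142857	0.142857	0.428571	0.285714	0.428571	0.285714	0.428571	0.285714	0.285714	0.857143	0.142857
I	0.428571	0.142857	0.142857	0.142857	0.428571	0.142857	0.142857	0	0.142857	1	0.857143	0.142857	0.714286	0.571429	0.142857	0.285714	0.428571	0.142857	0.428571	1
L	0.428571	0.285714	0.142857	0	0.428571	0.285714	0.142857	0	0.142857	0.857143	1	0.285714	0.857143	0.571429	0.142857	0.285714	0.428571	0.285714	0.428571	0.714286
K	0.428571	0.857143	0.571429	0.428571	0.142857	0.714286	0.714286	0.285714	0.428571	0.142857	0.285714	1	0.428571	0.142857	0.428571	0.571429	0.428571	0.142857	0.285714	0.285714
M	0.428571	0.428571	0.285714	0.142857	0.428571	0.571429	0.285714	0.142857	0.285714	0.714286	0.857143	0.428571	1	0.571429	0.285714	0.428571	0.428571	0.428571	0.428571	0.714286
F	0.285714	0.142857	0.142857	0.142857	0.285714	0.142857	0.142857	0.142857	0.428571	0.571429	0.571429	0.142857	0.571429	1	0	0.285714	0.285714	0.714286	1	0.428571
P	0.428571	0.285714	0.285714	0.428571	0.142857	0.428571	0.428571	0.285714	0.285714	0.142857	0.142857	0.428571	0.285714	0	1	0.428571	0.428571	0	0.142857	0.285714
S	0.714286	0.428571	0.714286	0.571429	0.428571	0.571429	0.571429	0.571429	0.428571	0.285714	0.285714	0.571429	0.428571	0.285714	0.428571	1	0.714286	0.142857	0.285714	0.285714
T	0.571429	0.428571	0.571429	0.428571	0.428571	0.428571	0.428571	0.285714	0.285714	0.428571	0.428571	0.428571	0.428571	0.285714	0.428571	0.714286	1	0.285714	0.285714	0.571429
W	0.142857	0.142857	0	0	0.285714	0.285714	0.142857	0.285714	0.285714	0.142857	0.285714	0.142857	0.428571	0.714286	0	0.142857	0.285714	1	0.857143	0.142857
Y	0.285714	0.285714	0.285714	0.142857	0.285714	0.428571	0.285714	0.142857	0.857143	0.428571	0.428571	0.285714	0.428571	1	0.142857	0.285714	0.285714	0.857143	1	0.428571
V	0.571429	0.142857	0.142857	0.142857	0.428571	0.285714	0.285714	0.142857	0.142857	1	0.714286	0.285714	0.714286	0.428571	0.285714	0.285714	0.571429	0.142857	0.428571	1
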