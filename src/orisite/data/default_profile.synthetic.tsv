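	ALA	ARG	ASN	ASP	CYS	GLN	GLU	GLY	HIS	ILE	LEU	LYS	MET	PHE	PRO	SER	THR	TRP	TYR	VAL
ALA	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
ARG	0	0	0	0.222222222222	0.111111111111	0.111111111111	0.111111111111	0	0.333333333333	0	0	0	0	0	0	0	0	0.111111111111	0	0
ASN	0	0	0	0	0.166666666667	0	0.333333333333	0.166666666667	0.333333333333	0	0	0	0	0	0	0	0	0	0	0
ASP	0	0.0606060606061	0	0.30303030303	0.030303030303	0	0.121212121212	0.030303030303	0.212121212121	0	0	0.0606060606061	0	0	0	0.121212121212	0.0606060606061	0	0	0
CYS	0	0.166666666667	0.166666666667	0.166666666667	0	0	0	0	0.333333333333	0	0	0	0	0	0	0	0	0	0.166666666667	0
GLN	0	0.5	0	0	0	0	0	0	0.5	0	0	0	0	0	0	0	0	0	0	0
GLU	0	0.0454545454545	0.0909090909091	0.181818181818	0	0	0.0909090909091	0.0454545454545	0.272727272727	0	0	0.136363636364	0.0454545454545	0	0	0.0454545454545	0	0	0.0454545454545	0
GLY	0	0	0.166666666667	0.166666666667	0	0	0.166666666667	0	0.166666666667	0	0	0.166666666667	0	0	0	0	0	0	0.166666666667	0
HIS	0	0.0697674418605	0.046511627907	0.162790697674	0.046511627907	0.0232558139535	0.139534883721	0.0232558139535	0.279069767442	0	0	0.0697674418605	0	0	0	0.093023255814	0	0.0232558139535	0.0232558139535	0
ILE	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
LEU	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
LYS	0	0	0	0.125	0	0	0.1875	0.0625	0.1875	0	0	0.125	0	0	0	0.125	0.0625	0	0.125	0
MET	0	0	0	0	0	0	1	0	0	0	0	0	0	0	0	0	0	0	0	0
PHE	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
PRO	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
SER	0	0	0	0.363636363636	0	0	0.0909090909091	0	0.363636363636	0	0	0.181818181818	0	0	0	0	0	0	0	0
THR	0	0	0	0.666666666667	0	0	0	0	0	0	0	0.333333333333	0	0	0	0	0	0	0	0
TRP	0	0.5	0	0	0	0	0	0	0.5	0	0	0	0	0	0	0	0	0	0	0
TYR	0	0	0	0	0.166666666667	0	0.166666666667	0.166666666667	0.166666666667	0	0	0.333333333333	0	0	0	0	0	0	0	0
VAL	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
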