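abbreviation	hemisphere	func_class	b
ORBmid	L	paralimbic	7.14
SPG	R	association	4.14
SPG	L	association	3.82
PCUN	R	association	3.55
OLF	L	paralimbic	3.47
THA	R	subcortical	3.22
PCL	R	association	2.98
PHG	L	paralimbic	2.98
ANG	R	association	2.92
MFG	L	association	2.88
ANG	L	association	2.85
PreCG	L	paralimbic	2.72
HIP	R	paralimbic	2.64
PHG	R	paralimbic	2.40
FFG	R	association	2.39
SMA	R	association	1.99
IFGtriang	L	association	1.98
MFG	R	association	1.95
INS	L	paralimbic	1.91
STG	R	association	1.85
SOG	L	association	1.53
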