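abbreviation	hemisphere	func_class	b
CUN	R	association	6.18
REC	R	association	4.42
MOG	L	association	4.38
INS	R	paralimbic	4.33
PoCG	L	paralimbic	3.92
SOG	L	association	3.21
HES	R	paralimbic	3.02
PHG	R	paralimbic	2.61
CAU	R	subcortical	2.40
TPOsup	L	paralimbic	2.15
ORBsupmed	L	paralimbic	2.04
HES	L	paralimbic	2.04
PCUN	L	association	1.95
PCUN	R	association	1.94
PHG	L	paralimbic	1.85
SPG	R	association	1.82
SMG	L	association	1.69
REC	L	association	1.61
OLF	R	paralimbic	1.57
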