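# RNA/RNA nearest-neighbor stack free energies, kcal/mol (37 C)
# top dimer 5'->3'; bottom dimer positionally aligned, read 3'->5'
top	bottom	dG
AA	UU	-0.93
AC	UG	-2.24
AG	UC	-2.08
AG	UU	-0.55
AU	UA	-1.10
AU	UG	-1.36
CA	GU	-2.11
CC	GG	-3.26
CG	GC	-2.36
CG	GU	-1.41
CU	GA	-2.08
CU	GG	-2.11
GA	CU	-2.35
GA	UU	-1.00
GC	CG	-3.42
GC	UG	-2.51
GG	CC	-3.26
GG	CU	-1.53
GG	UC	-2.11
GG	UU	-0.50
GU	CA	-2.24
GU	CG	-2.51
GU	UA	-1.36
GU	UG	0.47
UA	AU	-1.33
UA	GU	-1.27
UC	AG	-2.35
UC	GG	-1.53
UG	AC	-2.11
UG	AU	-1.27
UG	GC	-1.41
UG	GU	-0.57
UU	AA	-0.93
UU	AG	-1.00
UU	GA	-0.55
UU	GG	-0.50
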