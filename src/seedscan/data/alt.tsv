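# seedscan compact nearest-neighbor energy parameters (kcal/mol)
# stack rows: left-pair<TAB>right-pair<TAB>dG, dyads read 5'->3' on strand 1
[meta]
name	alt
temperature	310.15
[init]
init	4.00
[terminal]
end_penalty	0.50
[loop]
a	1.60
b	0.30
ml_close	2.80
ml_branch	0.50
[stack]
AU	AU	-1.00
AU	UA	-1.00
AU	CG	-2.20
AU	GC	-2.20
AU	GU	-0.65
AU	UG	-0.65
UA	AU	-1.00
UA	UA	-1.00
UA	CG	-2.20
UA	GC	-2.20
UA	GU	-0.65
UA	UG	-0.65
CG	AU	-2.20
CG	UA	-2.20
CG	CG	-3.40
CG	GC	-3.40
CG	GU	-1.85
CG	UG	-1.85
GC	AU	-2.20
GC	UA	-2.20
GC	CG	-3.40
GC	GC	-3.40
GC	GU	-1.85
GC	UG	-1.85
GU	AU	-0.65
GU	UA	-0.65
GU	CG	-1.85
GU	GC	-1.85
GU	GU	-0.30
GU	UG	-0.30
UG	AU	-0.65
UG	UA	-0.65
UG	CG	-1.85
UG	GC	-1.85
UG	GU	-0.30
UG	UG	-0.30
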