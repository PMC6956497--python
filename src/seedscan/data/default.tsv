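# seedscan compact nearest-neighbor energy parameters (kcal/mol)
# stack rows: left-pair<TAB>right-pair<TAB>dG, dyads read 5'->3' on strand 1
[meta]
name	default
temperature	310.15
[init]
init	4.10
[terminal]
end_penalty	0.45
[loop]
a	1.80
b	0.35
ml_close	3.00
ml_branch	0.40
[stack]
AU	AU	-1.10
AU	UA	-1.10
AU	CG	-2.05
AU	GC	-2.05
AU	GU	-0.80
AU	UG	-0.80
UA	AU	-1.10
UA	UA	-1.10
UA	CG	-2.05
UA	GC	-2.05
UA	GU	-0.80
UA	UG	-0.80
CG	AU	-2.05
CG	UA	-2.05
CG	CG	-3.00
CG	GC	-3.00
CG	GU	-1.75
CG	UG	-1.75
GC	AU	-2.05
GC	UA	-2.05
GC	CG	-3.00
GC	GC	-3.00
GC	GU	-1.75
GC	UG	-1.75
GU	AU	-0.80
GU	UA	-0.80
GU	CG	-1.75
GU	GC	-1.75
GU	GU	-0.50
GU	UG	-0.50
UG	AU	-0.80
UG	UA	-0.80
UG	CG	-1.75
UG	GC	-1.75
UG	GU	-0.50
UG	UG	-0.50
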