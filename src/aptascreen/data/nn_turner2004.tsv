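# Nearest-neighbor free-energy parameters (Turner 2004 rules, dG at 37 C, kcal/mol).
# version: turner2004-v1
# stack keys are "P/Q": helix step 5'-p1 q1-3' / 3'-p2 q2-5' where P = p1p2 (outer
# pair, 5' base first) and Q = q1q2 (inner pair). Wobble G.U steps included.
# hairpin keys are loop lengths (unpaired nt); terminal_au is the per-helix-end
# penalty for a closing A.U or G.U pair.
kind	key	value
stack	CG/CG	-3.30
stack	CG/GC	-2.40
stack	CG/GU	-1.40
stack	CG/UG	-2.10
stack	CG/AU	-2.10
stack	CG/UA	-2.10
stack	GC/CG	-3.40
stack	GC/GC	-3.30
stack	GC/GU	-1.50
stack	GC/UG	-2.50
stack	GC/AU	-2.40
stack	GC/UA	-2.20
stack	GU/CG	-2.50
stack	GU/GC	-2.10
stack	GU/GU	-0.50
stack	GU/UG	1.30
stack	GU/AU	-1.30
stack	GU/UA	-1.40
stack	UG/CG	-1.50
stack	UG/GC	-1.40
stack	UG/GU	0.30
stack	UG/UG	-0.50
stack	UG/AU	-1.00
stack	UG/UA	-0.60
stack	AU/CG	-2.20
stack	AU/GC	-2.10
stack	AU/GU	-0.60
stack	AU/UG	-1.40
stack	AU/AU	-0.90
stack	AU/UA	-1.10
stack	UA/CG	-2.40
stack	UA/GC	-2.10
stack	UA/GU	-1.00
stack	UA/UG	-1.30
stack	UA/AU	-1.30
stack	UA/UA	-0.90
hairpin	3	5.40
hairpin	4	5.60
hairpin	5	5.70
hairpin	6	5.40
hairpin	7	6.00
hairpin	8	5.50
hairpin	9	6.40
hairpin	10	6.50
hairpin	11	6.60
hairpin	12	6.70
hairpin	13	6.80
hairpin	14	6.90
hairpin	15	6.90
hairpin	16	7.00
hairpin	17	7.10
hairpin	18	7.10
hairpin	19	7.20
hairpin	20	7.20
hairpin	21	7.30
hairpin	22	7.30
hairpin	23	7.40
hairpin	24	7.40
hairpin	25	7.50
hairpin	26	7.50
hairpin	27	7.50
hairpin	28	7.60
hairpin	29	7.60
hairpin	30	7.70
misc	terminal_au	0.50
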