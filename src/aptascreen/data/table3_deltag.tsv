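sequence	name	length_nt	delta_g_kcal_mol	group
gaggucacugagaccau	ERaptR1	17	-5.70	aptamer
ccaggucacagugaccug	ERaptR2	18	-8.60	aptamer
agggucagggccaccug	ERaptR3	17	-4.40	aptamer
ggggucaaggugacccc	ERaptR4	17	-10.70	aptamer
aaggucacgguggccac	ERaptR5	17	-5.40	aptamer
uagcuuaucagacug	Random1	15	-0.21	random
gcugggaaacacccagg	Random2	17	-7.80	random
guugcauuuaggugcau	Random3	17	-4.30	random
cauagcagacagcuauc	Random4	17	-3.70	random
aauuuccacaggaaagca	Random5	18	-2.40	random
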