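gene_description	sequence	reference
Telomerase reverse transcriptase	TTGGTCAGGCTGATCTC	b40
Trefoil factor 1 (pS2)	AAGGTCACGGTGGCCAC	b41
Keratin-19	TAGGTCAGTAAGACCTC	b42
Oxytocin	GGGGTCAAGGTCACCGC	b43
Hageman Factor XII	TTGGTCAAGCTGCCCTC	b44
Complement C3	AGGGTCAGGGCCACCTG	b45
Lactotransferrin	CAGGTCAAGGCGATCTT	b46
Angiotensin	CGGGTCACGATGCCCTA	b47
Transforming growth factor, alpha (region -252 to -200)	GCGGTCACCGTCACCTC	b48,b49
Transforming growth factor, alpha (region -1527 to -1511)	GGGGTCAGCTGTGCCCCG	b48,b49
Vascular endothelial growth factor	CCAGTCAGTCTGATTAT	b50
Lipocalin-2	GAGGTCACTGAGACCAT	b51
Cathepsin D	CCGGTCACGTGGGCGCG	b52
Estrogen-Responsive Finger Protein	AGGGTCATGGTGACCCT	b53
Cytochrome c oxidase subunit VIIa related protein	GGGGTCAAGGTGACCCC	b54
Estrogen receptor binding site associated antigen 9	CGGGTCAGGGTGACCTC	b54,b55
Human genome Alu ERE	CAGGTCAAGGCGATCTT	b56
Solved crystal structure	CAGGTCACAGTGACCTG	b36
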