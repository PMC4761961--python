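candidate_id	sequence	z_av	z_h	z_p	z_t
ERaptR1	GAGGUCACUGAGACCAU	-2.04	-2.05	-1.62	-5.70
ERaptR2	CCAGGUCACAGUGACCUG	-1.56	-1.89	-1.87	-5.32
ERaptR3	AGGGUCAGGGCCACCUG	-2.21	-1.53	-1.54	-5.28
ERaptR4	GGGGUCAAGGUGACCCC	-1.76	-1.87	-1.27	-4.90
ERaptR5	AAGGUCACGGUGGCCAC	-1.36	-1.98	-1.45	-4.79
ERaptR6	UAGGUCAGUAAGACCUC	-1.89	-2.31	-0.57	-4.77
ERaptR7	CGGGUCACGAUGCCCUA	-1.90	-1.91	-0.95	-4.76
ERaptR8	CGGGUCAGGGUGACCUC	-1.78	-1.99	-0.98	-4.75
ERaptR9	UGGUCAGGCUGGUCUCA	-1.31	-1.38	-1.95	-4.63
ERaptR10	CCGGUCACGUGGGCGCG	-1.53	-1.44	-1.63	-4.60
ERaptR11	AGGGUCAUGGUGACCCU	-0.99	-1.74	-1.87	-4.59
ERaptR12	GGGGUCAAGGUCACCGC	-1.50	-1.61	-1.42	-4.52
ERaptR13	CAGGUCAAGGCGAUCUU	-1.67	-1.36	-1.23	-4.26
ERaptR14	CCAGUCAGUCUGAUUAU	-1.30	-2.02	-0.68	-4.00
ERaptR15	GCGGUCACCGUCACCUC	-1.41	-1.29	-0.76	-3.47
ERaptR16	UUGGUCAGGCUGAUCUC	-1.17	-1.84	-0.38	-3.38
ERaptR17	UUGGUCAAGCUGCCCUC	-1.33	-1.18	-0.73	-3.24
ERaptR18	GGGGUCAGCUGUGCCCCG	-1.12	-1.27	-0.51	-2.89
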