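name	n	ka_per_M	dh_kcal_mol	tds_kcal_mol	dg_kcal_mol
ERaptR1	0.4	9.20e7	-109.6	-98.6	-10.96
ERaptR2	0.5	7.60e7	-103.6	-92.6	-10.92
ERaptR3	0.4	5.24e7	119.3	-108.7	-10.53
ERaptR4	0.5	1.02e8	-100.2	-89.1	-11.10
ERaptR5	0.4	6.82e7	-97.2	-86.4	-10.78
ERaptR6	0.4	9.46e7	-89.5	-78.6	-10.82
ERaptR7	0.5	4.82e7	-84.8	-74.2	-10.60
ERaptR8	0.5	8.88e7	-117.8	-106.9	-10.81
ERaptR9	0.5	9.46e7	-97.2	-86.4	-10.78
ERaptR11	0.5	8.02e7	-104.7	-93.8	-10.83
ERaptR12	0.4	8.20e7	-100.5	-86.8	-10.80
ERaptR13	0.4	8.96e7	-89.7	-78.9	10.73
ERaptR14	0.3	7.42e7	-100.6	-89.6	-10.90
ERaptR15	0.3	9.25e7	-140.3	-129.3	-10.96
ERaptR16	0.4	9.40e7	-124.7	-113.8	-10.86
ERaptR17	0.4	1.26e8	-99.5	-88.5	-10.99
ERaptR18	0.3	9.91e7	-108.3	-97.7	-10.55
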