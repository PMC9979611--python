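conformer	parameter	exp	calc
I	A0	10341.5279	10311.35
I	B0	3876.1806	3865.70
I	C0	2912.3518	2904.74
I	chi_aa	-1.208	-1.336
I	chi_bb	-0.343	-0.448
I	chi_cc	1.551	1.785
I	mu_a	0.911	1.01
I	mu_b	0.607	0.66
I	mu_c	0.0	0.0
II	A0	10130.1521	10144.00
II	B0	4071.5120	4059.68
II	C0	3007.4852	2999.51
II	chi_aa	1.773	1.922
II	chi_bb	-3.194	-3.344
II	chi_cc	1.421	1.422
II	mu_a	5.372	5.39
II	mu_b	0.93	0.83
II	mu_c	0.0	0.03
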