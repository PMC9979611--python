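conformer	parameter	calc
IIgg	A0	3063.27
IIgg	B0	1600.59
IIgg	C0	1327.34
IIgg	chi_aa	-3.3302
IIgg	chi_bb	2.5198
IIgg	chi_cc	0.8104
IIgg	mu_a	1.40
IIgg	mu_b	3.98
IIgg	mu_c	-1.53
IIgg	dG0	0.0
Igg	A0	2874.44
Igg	B0	1615.60
Igg	C0	1366.95
Igg	chi_aa	-0.0280
Igg	chi_bb	0.3553
Igg	chi_cc	-0.3273
Igg	mu_a	-1.02
Igg	mu_b	-1.43
Igg	mu_c	-1.39
Igg	dG0	187.3
Ig-g	A0	4217.57
Ig-g	B0	1181.79
Ig-g	C0	1000.82
Ig-g	chi_aa	-4.5456
Ig-g	chi_bb	2.8019
Ig-g	chi_cc	1.7437
Ig-g	mu_a	-1.81
Ig-g	mu_b	0.37
Ig-g	mu_c	0.57
Ig-g	dG0	260.6
III'gg	A0	3223.13
III'gg	B0	1563.71
III'gg	C0	1267.50
III'gg	chi_aa	0.0509
III'gg	chi_bb	-0.5218
III'gg	chi_cc	0.4708
III'gg	mu_a	2.86
III'gg	mu_b	-2.42
III'gg	mu_c	1.36
III'gg	dG0	396.1
IIg-g-	A0	4352.34
IIg-g-	B0	1173.71
IIg-g-	C0	1012.74
IIg-g-	chi_aa	-0.1942
IIg-g-	chi_bb	2.2497
IIg-g-	chi_cc	-2.0555
IIg-g-	mu_a	2.33
IIg-g-	mu_b	-0.18
IIg-g-	mu_c	-0.20
IIg-g-	dG0	459.5
III'tg-	A0	2989.53
III'tg-	B0	1524.30
III'tg-	C0	1210.12
III'tg-	chi_aa	0.5818
III'tg-	chi_bb	-2.1507
III'tg-	chi_cc	1.5689
III'tg-	mu_a	-2.12
III'tg-	mu_b	0.31
III'tg-	mu_c	-0.02
III'tg-	dG0	574.3
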