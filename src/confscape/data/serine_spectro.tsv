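conformer	parameter	calc
Ig-g	A0	4461.34
Ig-g	B0	1823.01
Ig-g	C0	1441.95
Ig-g	chi_aa	-4.5535
Ig-g	chi_bb	2.8681
Ig-g	chi_cc	1.6854
Ig-g	mu_a	1.8574
Ig-g	mu_b	-0.2255
Ig-g	mu_c	0.7853
Ig-g	dG0	0.0
IIgg	A0	3549.33
IIgg	B0	2372.38
IIgg	C0	1734.67
IIgg	chi_aa	-3.6696
IIgg	chi_bb	2.1341
IIgg	chi_cc	1.5355
IIgg	mu_a	2.1328
IIgg	mu_b	-3.1566
IIgg	mu_c	-1.4660
IIgg	dG0	32.9
I'gg-	A0	3505.74
I'gg-	B0	2305.21
I'gg-	C0	1803.62
I'gg-	chi_aa	-0.9235
I'gg-	chi_bb	2.5528
I'gg-	chi_cc	-1.6293
I'gg-	mu_a	-0.4050
I'gg-	mu_b	-0.7361
I'gg-	mu_c	-2.7540
I'gg-	dG0	168.1
IItg-	A0	3630.86
IItg-	B0	2382.52
IItg-	C0	1515.28
IItg-	chi_aa	-3.8114
IItg-	chi_bb	2.1268
IItg-	chi_cc	1.6847
IItg-	mu_a	-0.7709
IItg-	mu_b	4.8433
IItg-	mu_c	-0.1467
IItg-	dG0	295.8
III'gg	A0	3950.32
III'gg	B0	2222.91
III'gg	C0	1657.03
III'gg	chi_aa	-0.6094
III'gg	chi_bb	-0.6702
III'gg	chi_cc	1.2796
III'gg	mu_a	-2.5568
III'gg	mu_b	-0.2893
III'gg	mu_c	-0.5279
III'gg	dG0	469.2
IIg-t	A0	4508.13
IIg-t	B0	1843.00
IIg-t	C0	1462.05
IIg-t	chi_aa	-0.3660
IIg-t	chi_bb	2.0569
IIg-t	chi_cc	-1.6909
IIg-t	mu_a	4.0962
IIg-t	mu_b	-1.7795
IIg-t	mu_c	0.2594
IIg-t	dG0	543.7
III'tg-	A0	3464.84
III'tg-	B0	2304.68
III'tg-	C0	1604.74
III'tg-	chi_aa	-1.0975
III'tg-	chi_bb	-0.6582
III'tg-	chi_cc	1.7557
III'tg-	mu_a	-2.8253
III'tg-	mu_b	-0.5939
III'tg-	mu_c	0.5548
III'tg-	dG0	617.6
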