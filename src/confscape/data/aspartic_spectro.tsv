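conformer	parameter	calc
IIgt	A0	2607.9
IIgt	B0	1188.9
IIgt	C0	1057.1
IIgt	chi_aa	-3.7322
IIgt	chi_bb	2.7326
IIgt	chi_cc	0.9996
IIgt	mu_a	2.3532
IIgt	mu_b	4.1392
IIgt	mu_c	-2.1974
IIgt	dG0	0.0
IIg-t	A0	3412.3
IIg-t	B0	900.4
IIg-t	C0	762.5
IIg-t	chi_aa	-3.4040
IIg-t	chi_bb	1.4552
IIg-t	chi_cc	1.9488
IIg-t	mu_a	3.6076
IIg-t	mu_b	2.1025
IIg-t	mu_c	1.4410
IIg-t	dG0	0.3
Igt	A0	2546.8
Igt	B0	1202.1
Igt	C0	1067.2
Igt	chi_aa	-0.2050
Igt	chi_bb	-0.2987
Igt	chi_cc	0.5037
Igt	mu_a	1.0967
Igt	mu_b	1.2332
Igt	mu_c	1.7069
Igt	dG0	50.4
I'g-t	A0	3372.8
I'g-t	B0	904.2
I'g-t	C0	778.1
I'g-t	chi_aa	1.1611
I'g-t	chi_bb	2.7491
I'g-t	chi_cc	-3.9102
I'g-t	mu_a	0.5375
I'g-t	mu_b	-1.8804
I'g-t	mu_c	-0.7507
I'g-t	dG0	123.1
III'gt	A0	2643.8
III'gt	B0	1182.9
III'gt	C0	1055.9
III'gt	chi_aa	-0.2629
III'gt	chi_bb	-0.3570
III'gt	chi_cc	0.6199
III'gt	mu_a	0.3702
III'gt	mu_b	0.5037
III'gt	mu_c	0.2090
III'gt	dG0	234.1
Ig-gc	A0	3192.2
Ig-gc	B0	943.8
Ig-gc	C0	781.4
Ig-gc	chi_aa	-4.1388
Ig-gc	chi_bb	2.5722
Ig-gc	chi_cc	1.5665
Ig-gc	mu_a	-5.2042
Ig-gc	mu_b	1.1751
Ig-gc	mu_c	-0.6972
Ig-gc	dG0	247.1
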