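row	label	dE_rDSD	dChS	dZPE_H	dTh_H	dZPE_anh_minus_H	TdS_QH_minus_H	dG	phi_prime	psi	omega	chi1	chi2	chi3	relaxes_to	barrier_cm1
IIgt	IIgt	0.0	0.0	0.0	0.0	0.0	0.0	0.0	36.3	20.7	-6.3	61.7	168.8	t
IIg-t	IIg-t	133.5	7.5	-57.1	-60.8	-13.1	-9.7	0.3	-35.7	20.0	-4.3	-65.5	174.7	t
Igt	Igt	288.7	-4.3	-143.6	-80.1	-17.3	7.0	50.4	179.6	-164.5	-177.8	67.8	-177.2	t
Ig-gc	Ig-gc	341.0	-4.1	7.3	-27.4	-38.8	-30.9	247.1	164.6	162.4	177.2	-63.0	38.8	c
III'gt	III'gt	350.5	83.5	-114.2	-99.3	-13.7	27.3	234.1	177.0	24.4	178.1	65.9	-179.7	t
I'g-t	I'g-t	478.9	-40.6	-178.2	-121.6	-24.5	9.1	123.1	86.6	-167.5	-177.0	-63.9	169.8	t
I'gg-c	I'gg-c	682.8	74.2	-4.4	18.0	-21.9	3.0	751.7	85.9	-179.1	-165.3	62.5	-36.9	c
IIItt	IIItt	777.4	9.7	-86.0	-25.3	-12.7	-65.0	598.1	169.6	5.1	167.2	-158.3	171.1	t
I'tt	I'tt	1136.3	-17.7	-202.4	-193.0	-17.3	51.1	757.0	62.7	-179.5	58.6	-173.7	-160.1	t
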