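row	label	dE_rDSD	dChS	dZPE_H	dTh_H	dZPE_anh_minus_H	TdS_QH_minus_H	dG	phi_prime	psi	omega	chi1	chi2	relaxes_to	barrier_cm1
IIgg	IIgg	0.0	0.0	0.0	0.0	0.0	0.0	0.0	-33.7	21.8	-6.1	60.0	77.1
Ig-g	Ig-g	218.5	34.5	-85.9	-83.0	27.7	20.4	132.2	162.5	143.7	177.8	-55.4	42.4
IItg-	IItg-	371.5	2.8	24.4	58.6	20.1	-30.5	446.9	-25.4	13.1	-2.3	-168.8	-53.7
I'gg-	I'gg-	459.8	-36.4	-93.7	13.4	21.3	-14.7	349.7	99.6	-175.8	-179.2	56.9	-47.3
III'g-g	III'g-g	574.6	45.8	-119.6	-135.4	44.4	45.4	455.2	168.2	-51.1	-179.4	-56.1	42.1
III'gg	III'gg	624.2	10.8	-76.8	-62.6	-37.4	4.4	462.6	-170.6	72.6	-176.4	57.8	65.8
IIg-t	IIg-t	711.2	9.2	-68.8	-25.5	7.5	-8.1	625.5	35.1	-21.0	5.4	-54.6	-177.8
IIgt	IIgt	586.1	6.9	-137.1	-104.9	-48.5	9.5	312.0	-26.2	11.5	-2.6	50.1	161.2	IIgg
IIg-g-	IIg-g-	725.9	24.4	-5.8	-9.0	0.1	-7.5	728.1	34.1	-21.8	6.1	-51.8	-84.1
Igt	Igt	962.3	8.8	-242.2	-137.4	4.0	8.4	603.9	-172.7	178.6	-179.4	64.0	179.4	Ig-g
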