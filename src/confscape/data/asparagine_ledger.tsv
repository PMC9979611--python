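row	label	dE_rDSD	dChS	dZPE_H	dTh_H	dZPE_anh_minus_H	TdS_QH_minus_H	dG	phi_prime	psi	omega	chi1	chi2	relaxes_to	barrier_cm1
IIgg	IIgg	0.0	0.0	0.0	0.0	0.0	0.0	0.0	-23.3	15.4	-4.9	58.5	101.0
IIg-t	IIg-t	727.6	-24.2	-222.8	-193.4	16.6	44.8	348.6	-36.9	20.5	-4.3	-65.6	177.0
Ig-g	Ig-g	826.9	27.3	-212.0	-260.1	81.8	82.5	546.4	172.4	161.0	177.3	-69.6	34.9
I'gg-	I'gg-	1016.6	8.8	-198.6	-62.1	61.6	24.1	850.4	80.6	-164.8	-178.6	69.8	-29.5
Igt	Igt	1072.6	-36.1	-367.2	-271.5	154.4	66.3	568.5	-179.7	-164.6	-178.0	67.1	-173.1
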