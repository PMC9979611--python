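row	label	dE_rDSD	dChS	dZPE_H	dTh_H	dZPE_anh_minus_H	TdS_QH_minus_H	dG	phi_prime	psi	omega	chi1	chi2	relaxes_to	barrier_cm1
IIgg	IIgg	0.0	0.0	0.0	0.0	0.0	0.0	0.0	-33.7	21.9	-6.2	59.4	79.3
Ig-g	Ig-g	161.8	11.2	-121.8	-113.1	21.3	7.7	-32.9	159.3	166.5	177.3	-55.9	44.1
IItg-	IItg-	222.2	11.4	24.3	54.7	-10.0	-39.7	262.9	-31.5	19.2	-4.5	-171.9	-54.2
I'gg-	I'gg-	337.7	-43.1	-122.4	-34.9	9.3	-11.4	135.2	95.1	-173.4	-180.0	57.1	-46.9
III'gg	III'gg	531.9	-0.4	-60.7	-54.6	10.9	9.6	436.7	-168.9	67.2	-177.1	59.4	68.6
IIg-t	IIg-t	602.4	32.2	-71.9	-28.3	15.9	-39.5	510.8	30.3	-14.2	2.4	-60.0	178.3
III'tg-	III'tg-	792.7	8.2	-32.6	-192.3	-2.7	11.4	584.7	178.0	64.9	-178.3	-178.4	-70.6
IIg-g-	IIg-g-	607.9	43.0	-46.5	-9.6	-12.6	-11.0	571.2	29.8	-15.7	3.4	-58.6	-76.9	IIg-t
III'g-g	III'g-g	731.9	34.1	-120.7	-197.7	5.3	61.9	514.8	165.8	-27.4	-176.7	-56.4	43.0	Ig-g	200
IIg-t#2	IIg-t	759.4	35.0	-129.3	-81.6	5.0	-14.0	574.5	-34.9	18.5	-3.6	-58.9	-174.3	IIg-t
Igt	Igt	853.1	4.5	-225.8	-131.5	6.5	5.3	512.1	-169.6	-179.6	-179.1	65.1	-175.6	I'gg-
Igg	Igg	869.3	-6.9	-188.3	-185.0	9.6	11.4	510.1	-164.3	-165.8	-176.5	66.4	83.3	III'gg
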