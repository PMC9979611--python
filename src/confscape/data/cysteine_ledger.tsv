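row	label	dE_rDSD	dChS	dZPE_H	dTh_H	dZPE_anh_minus_H	TdS_QH_minus_H	dG	phi_prime	psi	omega	chi1	chi2	relaxes_to	barrier_cm1
IIgg	IIgg	0.0	0.0	0.0	0.0	0.0	0.0	0.0	-32.7	18.6	-4.8	57.1	71.8
IIg-g-	IIg-g-	501.1	36.3	-24.6	-53.3	-7.6	-19.8	432.1	34.4	-18.0	4.0	-60.9	-65.4
Igg	Igg	571.1	-9.3	-177.6	-196.9	47.8	63.4	298.5	-171.3	-175.8	-177.4	63.7	74.7
Ig-g	Ig-g	630.7	8.9	-180.6	-198.4	10.0	28.8	299.4	162.9	162.6	177.5	-65.2	51.0
III'gg	III'gg	706.7	-18.5	-123.9	-168.2	1.6	65.4	463.1	-172.3	34.5	177.4	61.6	76.1
III'tg-	III'tg-	873.8	39.0	-153.0	-185.5	-22.5	39.7	591.5	175.6	85.6	-175.8	-175.4	-75.8
I'gg-	I'gg-	722.3	-44.1	-201.0	-85.4	1.2	-4.2	388.8	98.9	-173.0	179.8	64.3	-52.5	Ig-g
III'gg-	III'gg-	950.0	41.2	-79.1	-164.4	-15.2	19.3	751.8	114.0	79.9	-65.7	88.3	16.7
IIgt	IIgt	1056.5	-0.4	-38.8	-24.8	17.0	-13.8	995.7	152.9	1.8	-27.2	100.7	27.0
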