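conformer	parameter	exp	calc
IIgg	A0	3232.4827	3223.67
IIgg	B0	1533.71801	1528.34
IIgg	C0	1267.88615	1265.11
IIgg	chi_aa	-3.4971	-3.5846
IIgg	chi_bb	1.7519	1.7308
IIgg	chi_cc	1.7452	1.8538
IIgg	mu_a		2.85
IIgg	mu_b		2.95
IIgg	mu_c		-0.94
IIgg	dG0		0.0
Ig-g	A0	2872.77049	2864.48
Ig-g	B0	1608.95699	1602.22
Ig-g	C0	1211.39762	1214.77
Ig-g	chi_aa	-4.1859	-4.3527
Ig-g	chi_bb	2.661	2.6918
Ig-g	chi_cc	1.5248	1.6609
Ig-g	mu_a		-2.06
Ig-g	mu_b		0.01
Ig-g	mu_c		0.97
Ig-g	dG0		132.2
I'gg-	A0	3148.59247	3141.58
I'gg-	B0	1506.27679	1501.39
I'gg-	C0	1316.33575	1313.14
I'gg-	chi_aa	-0.7403	-0.2035
I'gg-	chi_bb	2.8781	2.9006
I'gg-	chi_cc	-2.1378	-2.6971
I'gg-	mu_a		-0.19
I'gg-	mu_b		-0.34
I'gg-	mu_c		-2.90
I'gg-	dG0		349.7
IItg-	A0	2670.72096	2671.88
IItg-	B0	1784.66894	1774.76
IItg-	C0	1383.75384	1376.76
IItg-	chi_aa	-3.7652	-4.1467
IItg-	chi_bb	2.4258	2.4728
IItg-	chi_cc	1.3394	1.6739
IItg-	mu_a		0.04
IItg-	mu_b		4.91
IItg-	mu_c		-0.16
IItg-	dG0		446.9
III'g-g	A0	2889.93352	2885.67
III'g-g	B0	1572.32152	1564.86
III'g-g	C0	1241.83423	1243.85
III'g-g	chi_aa	-4.1529	-4.2988
III'g-g	chi_bb	2.5682	2.5948
III'g-g	chi_cc	1.5846	1.7040
III'g-g	mu_a		-1.86
III'g-g	mu_b		1.58
III'g-g	mu_c		1.33
III'g-g	dG0		455.2
III'gg	A0	3379.841	3375.76
III'gg	B0	1482.04984	1474.72
III'gg	C0	1237.59121	1234.69
III'gg	chi_aa	-2.201	-2.2144
III'gg	chi_bb	-0.157	-0.2748
III'gg	chi_cc	2.358	2.4892
III'gg	mu_a		-2.23
III'gg	mu_b		0.98
III'gg	mu_c		-0.87
III'gg	dG0		462.6
IIg-t	A0	2912.6227	2907.62
IIg-t	B0	1660.21807	1656.40
IIg-t	C0	1189.31443	1187.62
IIg-t	chi_aa	-0.544	-0.3702
IIg-t	chi_bb	2.582	2.6214
IIg-t	chi_cc	-2.038	-2.2513
IIg-t	mu_a		3.78
IIg-t	mu_b		2.00
IIg-t	mu_c		0.19
IIg-t	dG0		625.5
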