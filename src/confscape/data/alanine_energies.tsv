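conformer	label	dE_ChS	dE_rDSD	dH0H	dG_H	dZPE_anh_minus_H	dTdS_QH_minus_H	dG
ttt	I	0.0	0.0	0.0	0.0	0.0	0.0	0.0
cg-c	II-	35.6	29.5	172.5	316.5	-28.1	-46.8	241.6
cgc	II	103.1	106.4	215.6	321.4	-26.7	-20.4	274.3
tg-t	III-	432.6	412.8	443.0	386.4	-12.5	42.1	416.0
tgt	III	436.0	410.1	452.1	329.9		-81.0
ga-t	I'	396.5	406.7	389.7	448.0	6.5	-25.7	428.8
gat	I'-	446.6	480.5	425.9	490.4	-8.1	-19.8	462.5
ggt	III'	613.5	655.6	592.4	631.7	4.0	-0.8	634.9
gg-t	III'-	789.7	782.7	774.3	804.6	1.3	-5.7	800.2
tsc	Ic	1736.0	1730.3	1681.6	1696.1	-0.7	-16.0	1679.4
ts-c	III-c	1980.5	1968.5	1928.2	2006.6	-54.3	-12.5	1839.8
g-tc	I'c	2116.5	2123.5	2052.8	2105.8	-28.1	-24.8	2052.9
gtc	I'-c	2154.9	2165.3	2043.0	1983.5	27.3	25.2	2036.0
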