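conformer	label	dE_best	dE_ChS	dE_rDSD	dH0H	dG_H	dZPE_anh_minus_H	dTdS_QH_minus_H	dG
ttt	I	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0
ccc	II*	223.8	236.5	214.8	345.9	468.8	-38.5	-29.4	400.9
gtt	I'*	433.7	431.5	447.8	406.6	482.6	-23.2	-39.5	419.9
tct	III	605.1	605.8	583.5	630.1	239.6	6.7	215.3	461.6
gct	III'*	926.8	935.5	918.9	937.5	969.4	-9.2	1.8	962.0
ttc	Ic	1678.8	1688.7	1675.4	1616.5	1659.6	1.9	-20.4	1641.1
tcc	IIIc	2042.5	2051.5	2071.3	2131.9	2027.3	-10.8	-15.2	2001.3
gtc	I'c*	2119.4	2118.9	2140.6	2012.3	2085.7	-28.8	-35.6	2021.3
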