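conformer	parameter	exp	calc
I	A0	5066.1455	5061.61
I	B0	3100.9507	3070.85
I	C0	2264.0131	2273.39
I	chi_aa	-3.2567	-3.4864
I	chi_bb	2.0093	1.9918
I	chi_cc	1.2474	1.4946
IIA	A0	4973.0546	4972.03
IIA	B0	3228.3375	3192.26
IIA	C0	2307.8090	2326.00
IIA	chi_aa	0.4515	0.8298
IIA	chi_bb	0.3267	0.4207
IIA	chi_cc	-0.7782	-1.2505
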