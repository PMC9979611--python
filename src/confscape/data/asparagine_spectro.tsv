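conformer	parameter	exp	calc
IIgg	A0	2270.85145	2258.22
IIgg	B0	1387.80238	1387.0
IIgg	C0	1102.63540	1101.81
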