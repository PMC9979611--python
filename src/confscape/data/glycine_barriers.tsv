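from	to	barrier_cm1
III	I	250
I'*	I	70
I'c*	Ic	25
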