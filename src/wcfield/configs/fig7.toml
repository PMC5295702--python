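# Hopf curve in the (J_e, J_i) plane, stimulation sigmoid, ramp protocol.
[point]
b_i = 8.0

[analysis]
beta = 3.0
ji_lo = 1.0
ji_hi = 6.0
ji_step = 0.25
je_end = 3.0
ramp_ms = 4000.0
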