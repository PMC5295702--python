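# Isolated pair, type II excitability: limit cycle, frequency-vs-current,
# branch diagram with envelopes.
[point]
b_i = 4.0

[analysis]
J_e_cycle = 2.0
je_lo = 1.3
je_hi = 3.0
je_step = 0.1
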