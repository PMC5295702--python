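# Propagation-regime survey of the type II medium over tau_i/tau_e.
[field]
dx = 0.02

[stimulus]
J_e = 1.3
width = 0.4

[analysis]
ratios = [2.0, 3.0, 3.9, 4.5, 6.0, 8.0, 10.0, 11.5, 12.5, 14.0, 16.0]
duration = 300.0
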