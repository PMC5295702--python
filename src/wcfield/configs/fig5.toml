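# n:1 wave emission from the focally converted type I medium.
[field]
b_i = 8.0
dx = 0.02

[stimulus]
J_i = 4.0
width = 0.4

[analysis]
J_e_values = [1.5, 2.2, 3.0]
duration = 450.0
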