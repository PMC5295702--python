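# Synthetic array recording emulating the beat-skipping in vivo data.
[synth]
n_skip = 2
f_src = 100.0
speed_cm_s = 18.9
pink_amp = 0.3
duration_s = 2.0
seed = 42
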