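# Single fish, quadratic drag: phase plane / period-vs-c (bursting from c~0.79)
a: 15.0
k: 0.8
c: 0.85
z1: 50.0
b0: 0.0
drag: quadratic
t_end: 500.0
transient: 250.0
pair: false
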