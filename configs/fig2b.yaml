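# Single fish, linear drag: period-vs-c curve (sweep --axis c over [0.9, 1.1])
a: 15.0
k: 0.4
c: 0.95
z1: 50.0
b0: 0.0
drag: linear
t_end: 500.0
transient: 250.0
pair: false
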