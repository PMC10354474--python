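# Coupled pair, quadratic drag: aperiodic leadership switching
a: 15.0
k: 0.8
c: 0.7885
z1: 50.0
b0: 0.0
drag: quadratic
d: 0.0125
z2: 0.15
x0: 15.0
gamma: 10.0
t_end: 4000.0
transient: 500.0
initial: [0.0, 0.0, 5.0, 0.0, 0.0, 0.0]
pair: true
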