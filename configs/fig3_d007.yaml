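# Coupled pair, linear drag, d=0.07: one of the five behavioural regimes.
# The same parameter set feeds the Lorenz maps and peak ACFs.
a: 15.0
k: 0.4
c: 0.9255
z1: 50.0
b0: 0.0
drag: linear
d: 0.07
z2: 0.15
x0: 15.0
gamma: 10.0
t_end: 4000.0
transient: 500.0
initial: [0.0, 0.0, 5.0, 0.0, 0.0, 0.0]
pair: true
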