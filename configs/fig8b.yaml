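# Heat-map bifurcation protocol at c=0.9255 (sweep --axis d --heatmap,
# grid 0 to 0.1 step 0.0005, 10 replicates with random x1 start)
a: 15.0
k: 0.4
c: 0.9255
z1: 50.0
b0: 0.0
drag: linear
d: 0.02
z2: 0.15
x0: 15.0
gamma: 10.0
t_end: 1000.0
transient: 250.0
pair: true
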