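# Two-genotype comparison preset: constant-size vs changing-size models
# at matched interior equilibria (N_H = 50, N_P = 150).
n: 2
N_H: 50
N_P: 150
w_H: 0.5
w_P: 1.0
alpha: 1.0
beta: 0.0
d_P: 1.0
b_H: 6.0
K: 100.0
lam0: 4.0
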