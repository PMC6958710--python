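# Five-genotype mutation regime: cyclic genotype conversion revives
# extinct genotypes, mixing negative frequency-dependent selection with
# arms-race sweeps. Initial sizes equal the interior equilibrium
# (N_H = 300, N_P = 900).
model: EcoEvoPlus
n: 5
N_H: 300
N_P: 900
w_H: 0.5
w_P: 1.0
alpha: 1.0
beta: 0.0
b_H: 6.0
d_P: 1.0
K: 600.0
lam0: 10.0
mut_H: 0.005
mut_P: 0.01
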