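# Parasite-population-size sweep preset. Constant-size models sweep N_P
# directly at fixed N_H; ecological models sweep the host birth rate b_H
# (interaction rate lam = lam0 / K fixed), which sets the equilibrium
# parasite size: N_P* = 2 b_H / lam for EcoEvo and half that for
# EcoEvoPlus, so the two grids below cover the same target N_P range.
n: 2
N_H: 250
K: 500.0
lam0: 4.0
d_P: 1.0
w_H: 0.5
w_P: 1.0
alpha: 1.0
beta: 0.0
sweep:
  EcoEvoPlus:
    axis: b_H
    values: [0.24, 0.32, 0.4, 0.48, 0.56, 0.64, 0.72, 0.8,
             0.88, 0.96, 1.04, 1.12, 1.2, 1.28, 1.36, 1.44, 1.52, 1.6]
  EcoEvo:
    axis: b_H
    values: [0.12, 0.16, 0.2, 0.24, 0.28, 0.32, 0.36, 0.4,
             0.44, 0.48, 0.52, 0.56, 0.6, 0.64, 0.68, 0.72, 0.76, 0.8]
  Hybrid:
    axis: N_P
    values: [30, 40, 50, 60, 70, 80, 90, 100, 110, 120,
             130, 140, 150, 160, 170, 180, 190, 200]
  Evo:
    axis: N_P
    values: [30, 40, 50, 60, 70, 80, 90, 100, 110, 120,
             130, 140, 150, 160, 170, 180, 190, 200]
  EvoPlus:
    axis: N_P
    values: [30, 40, 50, 60, 70, 80, 90, 100, 110, 120,
             130, 140, 150, 160, 170, 180, 190, 200]
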