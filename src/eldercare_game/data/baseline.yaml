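# Pinned baseline scenario for the three-mode elderly-care game.
# Sweep parameters (alpha1, lambda_H, lambda_G, b_G) and the extra costs
# (c_H, c_G) are set to the first value of their reference sweeps.
rho: 0.9
delta1: 0.1
delta2: 0.1
b: 3.0
b_G: 1.0
l1: 1.0
l2: 1.0
c_I: 1.5
c_M: 2.0
c_F: 2.0
c_H: 1.0
c_G: 1.0
alpha1: 0.5
lambda1: 1.0
lambda2: 1.0
lambda3: 2.0
lambda4: 2.0
lambda_H: 0.3
lambda_G: 0.3
beta: 3.49
beta_H: 28.7
beta_G: 7.71
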