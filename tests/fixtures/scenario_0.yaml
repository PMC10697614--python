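alpha1: 0.6547546864418147
b: 1.9350494519234218
b_G: 0.9812566855428873
beta: 3.364870586867413
beta_G: 4.004992321509281
beta_H: 16.127343565395314
c_F: 3.1273202237813487
c_G: 0.808607160681532
c_H: 1.9981889365375147
c_I: 1.785106518019889
c_M: 1.1297690710121984
delta1: 0.1765397533287087
delta2: 0.16234426840361404
l1: 1.935041239806982
l2: 1.1770257817096375
lambda1: 0.7993452110361425
lambda2: 1.9734239492038044
lambda3: 3.3930657788856253
lambda4: 1.2762661229637247
lambda_G: 0.28219020067899075
lambda_H: 0.33879285490250965
rho: 0.6041450407482751
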