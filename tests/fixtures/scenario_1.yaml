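alpha1: 0.7823631470650563
b: 4.995311874535105
b_G: 1.8646694817455471
beta: 5.792155853517156
beta_G: 5.913732735151951
beta_H: 21.88779802599793
c_F: 1.5036331381357493
c_G: 0.9244991530409776
c_H: 1.6776326537235455
c_I: 1.2797984424489024
c_M: 2.289453004295943
delta1: 0.14723658489923025
delta2: 0.13109223849562546
l1: 1.9346333023255744
l2: 0.7526549453744653
lambda1: 1.5370352204101096
lambda2: 1.2861391824703352
lambda3: 3.622506876206677
lambda4: 3.894709389135208
lambda_G: 0.49874010240382394
lambda_H: 0.15984062554312062
rho: 0.7585431056378135
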