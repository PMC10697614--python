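alpha1: 0.3054375035945696
b: 5.0062615407886915
b_G: 1.2275573607656967
beta: 5.6811728131497485
beta_G: 6.935483675632243
beta_H: 14.481121881113921
c_F: 3.3634483644186037
c_G: 1.2852743858231528
c_H: 1.7605072191316857
c_I: 2.2588852710688476
c_M: 2.6073084686231534
delta1: 0.17297870542263993
delta2: 0.19055628812337294
l1: 1.0089579683105447
l2: 0.8856643898318663
lambda1: 1.9329656021604182
lambda2: 1.5252906751033655
lambda3: 3.655891941759924
lambda4: 1.734994427965841
lambda_G: 0.4771321396124072
lambda_H: 0.2623291754209607
rho: 0.4836750711462198
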