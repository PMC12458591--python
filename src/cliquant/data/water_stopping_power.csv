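energy_kev,stopping_power_kev_per_cm,csda_range_cm
10,22560.0,2.515000e-04
20,13170.0,8.425164e-04
30,9653.0,1.735134e-03
40,7790.0,2.892033e-03
50,6603.0,4.289042e-03
60,5797.0,5.907416e-03
80,4757.0,9.727810e-03
100,4115.0,1.425645e-02
150,3238.0,2.803201e-02
200,2793.0,4.470206e-02
300,2355.0,8.387049e-02
400,2148.0,1.284146e-01
500,2034.0,1.762990e-01
600,1963.0,2.263688e-01
700,1916.0,2.779471e-01
800,1886.0,3.305613e-01
1000,1849.0,4.376993e-01
1250,1829.0,5.736716e-01
1500,1822.0,7.106286e-01
2000,1824.0,9.848946e-01
2500,1834.0,1.258241e+00
3000,1846.0,1.529954e+00
3500,1858.0,1.799911e+00
4000,1870.0,2.068133e+00
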