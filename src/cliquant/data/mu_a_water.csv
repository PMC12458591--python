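wavelength_nm,mu_a_per_cm
400,0.000066
425,0.000069
450,0.000092
475,0.000114
500,0.000204
525,0.000409
550,0.000565
575,0.000896
600,0.002224
625,0.002840
650,0.003400
675,0.004350
700,0.006240
725,0.015900
750,0.026200
775,0.024200
800,0.020200
825,0.028300
850,0.043000
875,0.056000
900,0.068000
925,0.144000
950,0.388000
975,0.450000
1000,0.360000
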