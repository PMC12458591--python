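wavelength_nm,mu_a_per_cm
400,0.052000
425,0.048000
450,0.037000
475,0.022000
500,0.012000
525,0.008000
550,0.006000
575,0.004000
600,0.003000
625,0.002500
650,0.002000
675,0.002000
700,0.002000
725,0.004000
750,0.005000
760,0.006000
775,0.005000
800,0.003000
825,0.003500
850,0.004000
875,0.008000
900,0.027000
930,0.108000
950,0.060000
975,0.030000
1000,0.025000
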