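wavelength_nm,mu_a_per_cm
400,1425.8891
410,2500.3082
420,2572.7188
430,1317.9159
440,549.3994
450,336.4308
460,238.2266
470,177.8612
480,142.6200
490,126.8471
500,112.1079
510,108.1071
520,129.6214
530,213.9969
540,285.1221
550,230.3857
560,174.6692
570,238.3123
580,268.3477
590,142.4647
600,17.1386
610,8.0659
620,5.0452
630,3.2670
640,2.3673
650,1.9709
660,1.7139
680,1.4889
700,1.5532
720,1.7888
740,2.3887
760,3.1385
780,3.8026
800,4.3703
820,5.0452
840,5.4736
860,5.8485
880,6.1806
900,6.4163
920,6.5984
940,6.5020
960,6.4163
980,6.2020
1000,5.8807
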