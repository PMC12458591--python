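wavelength_nm,mu_a_per_cm
400,1195.9318
410,1627.9318
420,2182.8155
430,2831.0833
440,2213.4508
450,553.2127
460,125.2618
470,86.5285
480,89.3564
490,106.6235
500,111.7330
510,138.0354
520,157.3806
530,209.0696
540,249.5381
550,286.0647
560,288.0785
570,241.3972
580,198.2722
590,210.1139
600,78.6073
610,50.5750
620,34.8610
630,27.5771
640,23.2710
650,20.0843
660,17.2832
680,12.8914
700,9.6083
720,6.6626
740,5.9771
760,8.9656
780,5.8164
800,4.0811
820,3.7116
840,3.7116
860,3.8883
880,3.9740
900,4.0811
920,4.6596
940,4.3114
960,3.7491
980,3.3206
1000,2.8600
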