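date,elapsed_day,L_original,L_adult_plus20,L_adult_minus20,L_brood_plus20,L_brood_minus20
2013-08-13,0,23.02,23.02,23.02,23.02,23.02
2013-08-24,11,21.26,25.51,17.01,21.26,21.26
2013-09-01,19,23.77,28.22,19.32,22.54,25.00
2013-09-05,23,25.14,29.69,20.59,23.21,27.07
2013-09-15,33,27.73,31.63,23.83,25.01,30.45
2013-09-21,39,27.08,31.14,21.90,22.65,31.32
2013-09-27,45,13.68,23.46,10.49,11.04,24.58
2013-10-04,52,14.39,14.39,14.39,12.48,17.31
2013-10-13,61,20.18,20.18,20.18,18.71,22.36
2013-10-27,75,31.34,31.34,31.34,30.33,32.83
2013-11-15,94,48.37,48.37,48.37,47.27,49.67
2013-12-01,110,62.34,62.34,62.34,61.58,63.49
2014-01-05,145,92.61,92.61,92.61,92.33,93.02
2014-02-07,178,0.00,0.00,0.00,0.00,0.00
2014-02-28,199,0.00,0.00,0.00,0.00,0.00
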