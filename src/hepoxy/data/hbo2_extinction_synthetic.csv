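# oxyhemoglobin, synthetic tabulation (Gaussian-band parameterization of landmark features); base-10 molar extinction per Hb tetramer (64,500 g/mol); hemoglobin amplitude scale 1.422171
wavelength_nm,epsilon_cm1_per_M
400,219165.79
401,259488.99
402,303469.29
403,350537.19
404,399905.24
405,450576.48
406,501368.29
407,550951.58
408,597904.50
409,640777.86
410,678168.32
411,708794.37
412,731569.38
413,745665.95
414,750566.21
415,746093.90
416,732425.34
417,710078.43
418,679880.64
419,642918.64
420,600473.97
421,553950.02
422,504796.03
423,454433.86
424,404192.63
425,355254.99
426,308617.90
427,265068.82
428,225177.25
429,189300.07
430,157598.25
431,130062.20
432,106542.33
433,86782.08
434,70450.52
435,57172.54
436,46555.12
437,38208.69
438,31763.39
439,26880.30
440,23258.22
441,20636.61
442,18795.56
443,17553.66
444,16764.37
445,16311.66
446,16105.43
447,16076.95
448,16174.68
449,16360.66
450,16607.31
451,16894.93
452,17209.61
453,17541.66
454,17884.38
455,18233.18
456,18584.88
457,18937.31
458,19288.91
459,19638.57
460,19985.44
461,20328.85
462,20668.21
463,21003.03
464,21332.83
465,21657.19
466,21975.68
467,22287.89
468,22593.41
469,22891.85
470,23182.82
471,23465.93
472,23740.81
473,24007.10
474,24264.43
475,24512.46
476,24750.85
477,24979.27
478,25197.41
479,25404.96
480,25601.64
481,25787.17
482,25961.30
483,26123.78
484,26274.38
485,26412.90
486,26539.14
487,26652.96
488,26754.19
489,26842.74
490,26918.51
491,26981.47
492,27031.61
493,27069.01
494,27093.78
495,27106.15
496,27106.47
497,27095.22
498,27073.08
499,27040.97
500,27000.10
501,26952.09
502,26899.02
503,26843.53
504,26789.00
505,26739.64
506,26700.66
507,26678.41
508,26680.59
509,26716.36
510,26796.49
511,26933.51
512,27141.72
513,27437.21
514,27837.81
515,28362.85
516,29032.92
517,29869.35
518,30893.72
519,32127.06
520,33589.00
521,35296.78
522,37264.12
523,39500.10
524,42007.98
525,44784.03
526,47816.62
527,51085.33
528,54560.46
529,58202.81
530,61963.86
531,65786.35
532,69605.42
533,73350.05
534,76945.01
535,80313.14
536,83377.91
537,86066.12
538,88310.71
539,90053.37
540,91247.08
541,91858.19
542,91868.10
543,91274.44
544,90091.57
545,88350.59
546,86098.65
547,83397.73
548,80322.94
549,76960.33
550,73404.48
551,69755.74
552,66117.42
553,62592.92
554,59282.86
555,56282.31
556,53678.19
557,51546.76
558,49951.42
559,48940.69
560,48546.45
561,48782.53
562,49643.71
563,51105.12
564,53122.21
565,55631.29
566,58550.75
567,61783.00
568,65217.12
569,68732.19
570,72201.25
571,75495.71
572,78490.07
573,81066.71
574,83120.56
575,84563.26
576,85326.69
577,85365.66
578,84659.45
579,83212.30
580,81052.63
581,78231.20
582,74818.23
583,70899.69
584,66573.10
585,61942.89
586,57115.83
587,52196.68
588,47284.23
589,42468.03
590,37825.91
591,33422.25
592,29307.12
593,25516.21
594,22071.42
595,18982.00
596,16246.16
597,13852.82
598,11783.64
599,10014.91
600,8519.41
601,7268.04
602,6231.25
603,5380.14
604,4687.38
605,4127.76
606,3678.62
607,3319.98
608,3034.61
609,2807.86
610,2627.55
611,2483.67
612,2368.11
613,2274.43
614,2197.56
615,2133.56
616,2079.42
617,2032.84
618,1992.10
619,1955.92
620,1923.35
621,1893.69
622,1866.42
623,1841.15
624,1817.60
625,1795.55
626,1774.83
627,1755.30
628,1736.84
629,1719.37
630,1702.80
631,1687.05
632,1672.06
633,1657.76
634,1644.09
635,1631.01
636,1618.45
637,1606.37
638,1594.72
639,1583.45
640,1572.53
641,1561.91
642,1551.55
643,1541.42
644,1531.48
645,1521.70
646,1512.06
647,1502.51
648,1493.05
649,1483.63
650,1474.24
651,1464.86
652,1455.46
653,1446.03
654,1436.55
655,1427.00
656,1417.38
657,1407.66
658,1397.84
659,1387.91
660,1377.85
661,1367.65
662,1357.32
663,1346.85
664,1336.22
665,1325.44
666,1314.50
667,1303.39
668,1292.13
669,1280.70
670,1269.11
671,1257.36
672,1245.44
673,1233.36
674,1221.13
675,1208.73
676,1196.19
677,1183.49
678,1170.66
679,1157.68
680,1144.56
681,1131.32
682,1117.95
683,1104.46
684,1090.86
685,1077.15
686,1063.34
687,1049.43
688,1035.45
689,1021.38
690,1007.23
691,993.03
692,978.76
693,964.45
694,950.09
695,935.69
696,921.27
697,906.82
698,892.36
699,877.90
700,863.43
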