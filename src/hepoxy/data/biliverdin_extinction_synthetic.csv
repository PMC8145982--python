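# biliverdin, synthetic stand-in shape (broad 377/670 nm bands); base-10 molar extinction
wavelength_nm,epsilon_cm1_per_M
400,12363.05
401,12224.24
402,12081.23
403,11934.23
404,11783.45
405,11629.07
406,11471.32
407,11310.39
408,11146.52
409,10979.89
410,10810.74
411,10639.28
412,10465.72
413,10290.27
414,10113.16
415,9934.60
416,9754.79
417,9573.96
418,9392.30
419,9210.02
420,9027.34
421,8844.44
422,8661.52
423,8478.78
424,8296.40
425,8114.58
426,7933.48
427,7753.29
428,7574.18
429,7396.30
430,7219.82
431,7044.89
432,6871.67
433,6700.28
434,6530.88
435,6363.58
436,6198.52
437,6035.81
438,5875.56
439,5717.88
440,5562.87
441,5410.62
442,5261.21
443,5114.73
444,4971.26
445,4830.85
446,4693.58
447,4559.49
448,4428.65
449,4301.09
450,4176.86
451,4055.98
452,3938.49
453,3824.41
454,3713.75
455,3606.54
456,3502.78
457,3402.48
458,3305.63
459,3212.23
460,3122.27
461,3035.75
462,2952.64
463,2872.92
464,2796.59
465,2723.60
466,2653.93
467,2587.55
468,2524.44
469,2464.54
470,2407.83
471,2354.26
472,2303.80
473,2256.40
474,2212.02
475,2170.61
476,2132.12
477,2096.52
478,2063.74
479,2033.74
480,2006.47
481,1981.88
482,1959.92
483,1940.54
484,1923.70
485,1909.33
486,1897.38
487,1887.82
488,1880.59
489,1875.63
490,1872.90
491,1872.36
492,1873.95
493,1877.63
494,1883.35
495,1891.07
496,1900.74
497,1912.31
498,1925.75
499,1941.02
500,1958.06
501,1976.85
502,1997.34
503,2019.49
504,2043.28
505,2068.65
506,2095.58
507,2124.03
508,2153.98
509,2185.38
510,2218.21
511,2252.43
512,2288.02
513,2324.96
514,2363.20
515,2402.73
516,2443.51
517,2485.54
518,2528.77
519,2573.19
520,2618.78
521,2665.51
522,2713.37
523,2762.32
524,2812.36
525,2863.46
526,2915.60
527,2968.78
528,3022.96
529,3078.13
530,3134.27
531,3191.38
532,3249.43
533,3308.40
534,3368.28
535,3429.07
536,3490.73
537,3553.26
538,3616.64
539,3680.86
540,3745.90
541,3811.75
542,3878.39
543,3945.82
544,4014.01
545,4082.96
546,4152.65
547,4223.06
548,4294.18
549,4366.00
550,4438.50
551,4511.67
552,4585.49
553,4659.95
554,4735.03
555,4810.72
556,4887.01
557,4963.87
558,5041.29
559,5119.26
560,5197.76
561,5276.77
562,5356.27
563,5436.26
564,5516.70
565,5597.59
566,5678.91
567,5760.63
568,5842.74
569,5925.22
570,6008.06
571,6091.22
572,6174.70
573,6258.46
574,6342.50
575,6426.79
576,6511.31
577,6596.04
578,6680.95
579,6766.03
580,6851.25
581,6936.59
582,7022.03
583,7107.54
584,7193.10
585,7278.69
586,7364.28
587,7449.85
588,7535.38
589,7620.84
590,7706.20
591,7791.44
592,7876.54
593,7961.46
594,8046.19
595,8130.70
596,8214.96
597,8298.95
598,8382.63
599,8465.99
600,8549.00
601,8631.62
602,8713.84
603,8795.63
604,8876.95
605,8957.79
606,9038.11
607,9117.89
608,9197.11
609,9275.72
610,9353.72
611,9431.06
612,9507.73
613,9583.70
614,9658.94
615,9733.42
616,9807.12
617,9880.01
618,9952.06
619,10023.25
620,10093.55
621,10162.94
622,10231.39
623,10298.88
624,10365.38
625,10430.86
626,10495.30
627,10558.68
628,10620.97
629,10682.16
630,10742.20
631,10801.09
632,10858.80
633,10915.31
634,10970.59
635,11024.63
636,11077.40
637,11128.88
638,11179.05
639,11227.90
640,11275.40
641,11321.53
642,11366.27
643,11409.62
644,11451.55
645,11492.03
646,11531.07
647,11568.64
648,11604.72
649,11639.30
650,11672.38
651,11703.92
652,11733.93
653,11762.38
654,11789.28
655,11814.60
656,11838.33
657,11860.47
658,11881.01
659,11899.94
660,11917.24
661,11932.92
662,11946.97
663,11959.38
664,11970.14
665,11979.26
666,11986.72
667,11992.53
668,11996.68
669,11999.17
670,12000.00
671,11999.17
672,11996.68
673,11992.53
674,11986.72
675,11979.26
676,11970.14
677,11959.38
678,11946.97
679,11932.92
680,11917.24
681,11899.94
682,11881.01
683,11860.47
684,11838.33
685,11814.60
686,11789.28
687,11762.38
688,11733.93
689,11703.92
690,11672.38
691,11639.30
692,11604.72
693,11568.64
694,11531.07
695,11492.03
696,11451.54
697,11409.62
698,11366.27
699,11321.53
700,11275.39
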