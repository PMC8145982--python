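# deoxyhemoglobin, synthetic tabulation (Gaussian-band parameterization of landmark features); base-10 molar extinction per Hb tetramer (64,500 g/mol); hemoglobin amplitude scale 1.422171
wavelength_nm,epsilon_cm1_per_M
400,4081.17
401,4277.02
402,4504.08
403,4782.02
404,5143.21
405,5639.38
406,6350.92
407,7399.15
408,8961.60
409,11289.99
410,14729.40
411,19736.42
412,26892.52
413,36907.56
414,50607.91
415,68903.06
416,92726.00
417,122945.30
418,160251.07
419,205022.35
420,257189.87
421,316113.08
422,380494.13
423,448350.71
424,517065.69
425,583522.04
426,644319.38
427,696054.16
428,735632.98
429,760579.36
430,769291.96
431,761216.79
432,736907.63
433,697965.58
434,646866.90
435,586704.77
436,520882.53
437,452800.33
438,385574.96
439,321823.36
440,263527.58
441,211985.29
442,167836.78
443,131151.13
444,101549.06
445,78340.24
446,60655.88
447,47562.76
448,38151.19
449,31594.57
450,27182.81
451,24334.23
452,22592.02
453,21610.89
454,21138.90
455,20998.30
456,21067.56
457,21266.08
458,21541.91
459,21862.50
460,22207.95
461,22566.40
462,22930.91
463,23297.46
464,23663.75
465,24028.43
466,24390.67
467,24749.93
468,25105.80
469,25457.96
470,25806.13
471,26150.05
472,26489.46
473,26824.12
474,27153.81
475,27478.30
476,27797.37
477,28110.82
478,28418.44
479,28720.05
480,29015.48
481,29304.56
482,29587.14
483,29863.11
484,30132.34
485,30394.76
486,30650.30
487,30898.93
488,31140.66
489,31375.54
490,31603.65
491,31825.15
492,32040.24
493,32249.22
494,32452.45
495,32650.40
496,32843.65
497,33032.91
498,33219.05
499,33403.09
500,33586.25
501,33769.94
502,33955.84
503,34145.86
504,34342.22
505,34547.42
506,34764.32
507,34996.12
508,35246.41
509,35519.16
510,35818.76
511,36149.99
512,36518.05
513,36928.52
514,37387.38
515,37900.92
516,38475.74
517,39118.67
518,39836.71
519,40636.91
520,41526.28
521,42511.68
522,43599.67
523,44796.36
524,46107.24
525,47537.02
526,49089.44
527,50767.10
528,52571.27
529,54501.73
530,56556.57
531,58732.08
532,61022.61
533,63420.45
534,65915.79
535,68496.68
536,71149.02
537,73856.65
538,76601.40
539,79363.27
540,82120.63
541,84850.43
542,87528.51
543,90129.92
544,92629.26
545,95001.09
546,97220.30
547,99262.57
548,101104.76
549,102725.30
550,104104.62
551,105225.49
552,106073.33
553,106636.51
554,106906.55
555,106878.31
556,106550.09
557,105923.62
558,105004.09
559,103800.00
560,102323.02
561,100587.77
562,98611.52
563,96413.90
564,94016.51
565,91442.55
566,88716.40
567,85863.23
568,82908.56
569,79877.84
570,76796.12
571,73687.65
572,70575.56
573,67481.60
574,64425.86
575,61426.63
576,58500.20
577,55660.79
578,52920.49
579,50289.27
580,47774.98
581,45383.43
582,43118.51
583,40982.28
584,38975.18
585,37096.10
586,35342.65
587,33711.29
588,32197.52
589,30796.05
590,29500.99
591,28306.01
592,27204.49
593,26189.62
594,25254.60
595,24392.66
596,23597.22
597,22861.90
598,22180.65
599,21547.74
600,20957.82
601,20405.92
602,19887.50
603,19398.40
604,18934.88
605,18493.58
606,18071.50
607,17666.01
608,17274.80
609,16895.86
610,16527.47
611,16168.14
612,15816.63
613,15471.89
614,15133.05
615,14799.40
616,14470.36
617,14145.48
618,13824.40
619,13506.86
620,13192.65
621,12881.64
622,12573.76
623,12268.96
624,11967.23
625,11668.58
626,11373.08
627,11080.76
628,10791.70
629,10505.98
630,10223.69
631,9944.91
632,9669.74
633,9398.26
634,9130.58
635,8866.77
636,8606.91
637,8351.11
638,8099.42
639,7851.92
640,7608.69
641,7369.77
642,7135.23
643,6905.13
644,6679.49
645,6458.37
646,6241.80
647,6029.80
648,5822.40
649,5619.62
650,5421.46
651,5227.93
652,5039.02
653,4854.75
654,4675.08
655,4500.02
656,4329.53
657,4163.60
658,4002.18
659,3845.26
660,3692.79
661,3544.73
662,3401.03
663,3261.64
664,3126.52
665,2995.59
666,2868.82
667,2746.12
668,2627.45
669,2512.73
670,2401.89
671,2294.86
672,2191.56
673,2091.94
674,1995.89
675,1903.36
676,1814.26
677,1728.52
678,1646.04
679,1566.76
680,1490.59
681,1417.44
682,1347.24
683,1279.91
684,1215.37
685,1153.53
686,1094.31
687,1037.63
688,983.42
689,931.60
690,882.08
691,834.79
692,789.66
693,746.61
694,705.57
695,666.46
696,629.22
697,593.77
698,560.05
699,527.99
700,497.52
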