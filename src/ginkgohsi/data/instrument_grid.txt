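# Band-center wavelengths (nm), one per line, for the 231-channel
# VNIR instrument fixture grid (400-1000 nm).
400.000000
402.642857
405.285714
407.928571
410.571429
413.214286
415.857143
418.500000
421.142857
423.785714
426.428571
429.071429
431.714286
434.357143
437.000000
439.750000
442.397250
445.044500
447.691750
450.339000
452.986250
455.633500
458.280750
460.928000
463.575250
466.222500
468.869750
471.517000
474.164250
476.811500
479.458750
482.106000
484.753250
487.400500
490.047750
492.695000
495.342250
497.989500
500.636750
503.284000
505.931250
508.578500
511.225750
513.873000
516.520250
519.167500
521.814750
524.462000
527.109250
529.756500
532.403750
535.051000
537.698250
540.345500
542.992750
545.640000
548.354561
551.069123
553.783684
556.498246
559.212807
561.927368
564.641930
567.356491
570.071053
572.785614
575.500175
578.214737
580.929298
583.643860
586.358421
589.072982
591.787544
594.502105
597.216667
599.931228
602.645789
605.360351
608.074912
610.789474
613.504035
616.218596
618.933158
621.647719
624.362281
627.076842
629.791404
632.505965
635.220526
637.935088
640.649649
643.364211
646.078772
648.793333
651.507895
654.222456
656.937018
659.651579
662.366140
665.080702
667.795263
670.509825
673.224386
675.938947
678.653509
681.368070
684.082632
686.797193
689.511754
692.226316
694.940877
697.655439
700.370000
703.051351
705.732703
708.414054
711.095405
713.776757
716.458108
719.139459
721.820811
724.502162
727.183514
729.864865
732.546216
735.227568
737.908919
740.590270
743.271622
745.952973
748.634324
751.315676
753.997027
756.678378
759.359730
762.041081
764.722432
767.403784
770.085135
772.766486
775.447838
778.129189
780.810541
783.491892
786.173243
788.854595
791.535946
794.217297
796.898649
799.580000
802.261351
804.942703
807.624054
810.305405
812.986757
815.668108
818.349459
821.030811
823.712162
826.393514
829.074865
831.756216
834.437568
837.118919
839.800270
842.481622
845.162973
847.844324
850.525676
853.207027
855.888378
858.569730
861.251081
863.932432
866.613784
869.295135
871.976486
874.657838
877.339189
880.020541
882.701892
885.383243
888.064595
890.745946
893.427297
896.108649
898.790000
901.471351
904.152703
906.834054
909.515405
912.196757
914.878108
917.559459
920.240811
922.922162
925.603514
928.284865
930.966216
933.647568
936.328919
939.010270
941.691622
944.372973
947.054324
949.735676
952.417027
955.098378
957.779730
960.461081
963.142432
965.823784
968.505135
971.186486
973.867838
976.549189
979.230541
981.911892
984.593243
987.274595
989.955946
992.637297
995.318649
998.000000
998.285714
998.571429
998.857143
999.142857
999.428571
999.714286
1000.000000
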