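activity_class,SQB(C./T1),SQB(C./T2),SQB(C./T3),SQB(R.),TAN
466,5.17,8.28,8.62,6.9,5.86
548,22.07,24.14,24.14,21.03,22.76
600,13.1,14.83,16.21,10.34,11.38
644,14.14,17.93,17.93,17.24,17.59
652,7.59,8.97,9.66,8.62,7.93
689,8.28,11.38,11.72,8.28,9.66
692,3.79,5.17,4.83,6.21,4.83
712,9.31,12.41,11.03,16.9,10.34
713,7.59,6.55,5.86,7.24,7.24
733,9.31,8.62,8.62,8.97,8.97
737,8.97,8.62,8.28,12.41,8.28
810,7.24,10.34,11.03,10.34,6.9
832,13.1,14.83,14.83,11.38,13.1
846,25.86,25.86,26.9,23.45,28.62
852,19.31,20,20,18.62,21.38
858,5.17,6.21,6.21,7.93,5.86
859,7.93,10,8.62,10.69,8.97
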