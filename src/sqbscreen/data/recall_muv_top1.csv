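activity_class,SQB(C./T1),SQB(C./T2),SQB(C./T3),SQB(R.),TAN
466,2.41,1.03,1.38,2.41,3.1
548,8.28,10.34,11.38,7.59,8.62
600,3.79,4.48,5.52,2.41,3.79
644,7.59,8.28,8.97,7.24,7.59
652,2.76,4.14,3.79,2.07,2.76
689,3.79,5.17,4.48,2.07,3.79
692,0.69,1.03,1.38,0.69,0.69
712,3.45,4.48,5.17,4.14,4.14
713,2.76,2.76,2.76,2.41,3.1
733,3.45,4.14,4.14,1.38,3.45
737,2.41,1.72,1.72,1.38,2.41
810,1.72,2.41,1.72,2.41,2.07
832,6.21,7.24,8.28,4.48,6.55
846,10.34,12.76,12.41,8.97,9.66
852,9.66,9.31,9.66,8.62,12.41
858,1.72,1.38,1.38,3.1,1.72
859,1.72,2.07,2.41,2.07,1.38
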