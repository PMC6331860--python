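activity_class,SQB(C./T1),SQB(C./T2),SQB(C./T3),SQB(R.),TAN
31420,72.18,72.44,73.73,70.03,69.69
71523,26.33,25.41,26.84,25.58,25.94
37110,18.33,22.09,24.73,9,9.63
31432,41.61,37.2,36.66,37.34,35.82
42731,19.06,20.49,21.17,17.34,17.77
06233,12.45,12.26,12.49,10.75,13.87
06245,7.18,6.37,6.03,6.03,6.51
07701,10.33,10.91,11.35,8.25,8.63
06235,10.51,10.9,10.15,9.14,9.71
78374,12.46,11.77,13.08,13.65,13.69
78331,6.08,6.54,5.92,5.78,7.17
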