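activity_class,SQB(C./T1),SQB(C./T2),SQB(C./T3),SQB(R.),TAN
31420,87.75,87.24,87.22,84.03,83.49
71523,60.16,48.48,48.7,48.65,48.92
37110,39.81,45.77,45.62,19.56,21.01
31432,82,70.57,70.44,76.48,74.29
42731,28.77,24.58,24.35,28.19,29.68
06233,20.96,19.04,20.04,21.04,27.68
06245,15.39,13.99,13.72,13.63,16.54
07701,26.9,25.41,26.73,21.85,24.09
06235,22.47,23.72,22.81,19.13,20.06
78374,20.95,20.73,19.56,20.55,20.51
78331,10.31,11.48,11.37,13.1,16.2
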