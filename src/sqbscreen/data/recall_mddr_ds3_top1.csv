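activity_class,SQB(C./T1),SQB(C./T2),SQB(C./T3),SQB(R.),TAN
09249,10.17,10.61,10.99,9.92,12.12
12455,5.65,6.65,7.03,5.12,6.57
12464,5.04,6.17,6.92,5.56,8.17
31281,15.14,18.19,18.67,10.29,16.95
43210,5.77,6.93,6.83,5.31,6.27
71522,4.74,6.34,6.57,3.03,3.75
75721,18.44,20.14,20.38,15.24,17.32
78331,6.16,6.03,6.16,5.48,6.31
78348,8.03,8,8.99,9.67,10.15
78351,10.87,11.98,12.5,10.03,9.84
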