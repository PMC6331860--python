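activity_class,SQB(C./T1),SQB(C./T2),SQB(C./T3),SQB(R.),TAN
09249,18.05,18.26,17.8,21.4,24.17
12455,7.59,10.23,11.42,8.1,10.29
12464,12.78,16.09,16.79,10.56,15.22
31281,20.86,27.43,29.05,15.14,29.62
43210,11.83,13.54,14.12,14.47,16.07
71522,10.56,13.26,13.82,9.2,12.37
75721,25.1,30.13,30.61,22.27,25.21
78331,10.16,12.11,11.97,12.03,15.01
78348,20,21.89,21.14,22.72,24.67
78351,11.8,12.63,13.3,11.95,11.71
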