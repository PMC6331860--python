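activity_class,SQB(C./T1),SQB(C./T2),SQB(C./T3),SQB(R.),TAN
FGFR1T,6.75,6.5,7,6.17,6.67
FXA,8.84,7.74,8.29,8.08,7.88
GART,23,22.75,23.25,22.25,22.25
GBP,28.65,30.58,30.96,21.35,20.96
GR,6.79,8.21,8.46,6.67,6.41
HIVPR,13.23,10.97,11.29,11.45,11.77
HIVRT,5.58,6.74,6.98,4.65,4.88
HMGA,10.86,11.43,13.14,10.29,10.29
HSP90,9.19,9.19,8.38,8.11,8.11
MR,8.67,9.33,10,9.33,9.33
NA,6.33,9.59,9.8,4.9,5.1
PR,5.19,6.67,5.19,4.44,4.81
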