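activity_class,SQB(C./T1),SQB(C./T2),SQB(C./T3),SQB(R.),TAN
FGFR1T,2.67,2.92,2.92,2.33,2.5
FXA,3.15,3.36,3.36,2.26,1.92
GART,5.25,5.75,5.75,7.5,7.75
GBP,15.77,16.73,15.96,13.65,13.27
GR,2.18,3.46,3.21,2.31,2.31
HIVPR,4.52,2.74,3.55,3.39,3.55
HIVRT,1.86,1.86,1.86,1.63,1.63
HMGA,6.57,5.43,5.43,5.71,6.29
HSP90,3.78,4.05,4.05,2.16,1.62
MR,5.33,5.33,5.33,5.33,5.33
NA,3.06,4.9,5.31,2.24,2.24
PR,2.22,2.22,2.22,1.85,1.85
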