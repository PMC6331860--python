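activity_class,SQB(C./T1),SQB(C./T2),SQB(C./T3),SQB(R.),TAN
07707,75.15,74.22,74.37,70.39,70.39
07708,99.87,100,99.61,64.97,56.58
31420,95.04,95.24,94.88,87.04,88.19
42710,91.09,93,91.09,89.18,88.09
64100,99.23,98.94,99.03,94.59,93.75
64200,95.18,98.93,99.38,81.34,77.68
64220,84.06,90.9,90.62,48.11,52.19
64500,83.28,92.72,92.48,47.68,44.8
64350,96.02,93.75,90.78,87.96,91.71
75755,98.17,98.39,98.37,94.07,94.82
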