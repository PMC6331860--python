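activity_class,SQB(C./T1),SQB(C./T2),SQB(C./T3),SQB(R.),TAN
07707,72.62,71.31,72.09,58.5,61.84
07708,95.87,96.06,95.68,55.61,47.03
31420,72.02,71.32,78.56,62.22,65.1
42710,82.18,77.45,76.82,83,81.27
64100,88.9,87.92,87.8,80.73,80.31
64200,63.3,70,70.18,53.13,53.84
64220,60.9,66.79,67.58,34.61,38.64
64500,67.36,78.64,79.2,29.04,30.56
64350,82.45,80.83,81.68,81.86,80.18
75755,97.6,97.91,98.02,85.4,87.56
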