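band,population
30-34,4650000
35-39,4100000
40-44,3400000
45-49,2800000
50-54,2350000
55-59,1950000
60-64,1550000
65-69,1150000
70-74,800000
75+,900000
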