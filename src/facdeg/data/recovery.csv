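level_mg,day,replicate,amount_found_mg
80,1,1,78.34
80,1,2,79.43
80,1,3,81.33
80,2,1,79.24
80,2,2,81.09
80,2,3,80.11
80,3,1,80.39
80,3,2,80.43
80,3,3,82.72
100,1,1,101.69
100,1,2,99.68
100,1,3,100.72
100,2,1,98.75
100,2,2,97.83
100,2,3,101.06
100,3,1,99.85
100,3,2,102.79
100,3,3,104.03
120,1,1,118.11
120,1,2,120.36
120,1,3,119.62
120,2,1,120.16
120,2,2,119.88
120,2,3,117.44
120,3,1,119.86
120,3,2,120.43
120,3,3,123.34
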