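reo,d_plus,d_minus,ci_printed,rank_printed
MJU,0.2789,0.0661,0.1915,5
DM,0.0204,0.3286,0.9416,1
AL,0.2272,0.1492,0.3963,4
MP,0.3256,0.0256,0.0730,6
MO,0.1449,0.2099,0.5917,2
BL,0.1843,0.1826,0.4977,3
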