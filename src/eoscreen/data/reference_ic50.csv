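sample,cell_line,ic50_mg_ml,sd
α-Pinene,HaCaT,0.580,0.039
Camphor,HaCaT,0.986,0.075
Bornyl acetate,HaCaT,1.321,0.080
Verbenone,HaCaT,2.021,0.158
"1,8-Cineole",HaCaT,3.202,0.130
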