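no,compound,compound_class,oxygenated,ri_calculated,ri_reference,MJU,DM,AL,MP,MO,BL,evidence
1,α-Thujene,monoterpene_hydrocarbon,no,926,924,0.34 ± 0.29,-,-,-,-,-,"MS,RI"
2,α-Pinene,monoterpene_hydrocarbon,no,933,932,42.81 ± 2.52,33.15 ± 1.98,7.51 ± 0.11,18.07 ± 1.28,8.94 ± 0.16,9.17 ± 0.79,"MS,RI,AC"
3,Camphene,monoterpene_hydrocarbon,no,946,946,6.99 ± 0.26,2.45 ± 0.33,1.59 ± 0.18,4.56 ± 0.19,6.06 ± 0.22,2.52 ± 0.26,"MS,RI,AC"
4,"Thuja-2,4(10)-diene",monoterpene_hydrocarbon,no,952,953,-,0.37 ± 0.02,-,-,-,0.55 ± 0.05,"MS,RI"
5,β-Pinene,monoterpene_hydrocarbon,no,974,974,0.92 ± 0.20,0.89 ± 0.05,1.19 ± 0.28,0.78 ± 0.02,1.14 ± 0.11,0.29 ± 0.26,"MS,RI,AC"
6,3-Octanone,miscellaneous,yes,987,986,1.51 ± 0.10,-,-,-,-,-,"MS,RI"
7,Myrcene,monoterpene_hydrocarbon,no,992,988,3.35 ± 0.46,0.82 ± 0.06,8.05 ± 0.86,0.30 ± 0.01,2.58 ± 0.04,0.56 ± 0.11,"MS,RI,AC"
8,3-Carene,monoterpene_hydrocarbon,no,1009,1008,-,-,-,-,0.71 ± 0.08,-,"MS,RI"
9,α-Terpinene,monoterpene_hydrocarbon,no,1016,1017,0.34 ± 0.30,0.53 ± 0.04,-,-,-,-,"MS,RI,AC"
10,p-Cymene,monoterpene_hydrocarbon,no,1024,1025,2.61 ± 0.22,1.30 ± 0.25,10.51 ± 0.70,2.78 ± 0.27,3.02 ± 0.26,2.16 ± 0.02,"MS,RI,AC"
11,Limonene,monoterpene_hydrocarbon,no,1028,1030,3.31 ± 0.31,2.61 ± 0.43,7.04 ± 0.40,3.48 ± 0.34,3.12 ± 0.30,2.37 ± 0.44,"MS,RI,AC"
12,"1,8-Cineole",monoterpene_ether,yes,1031,1032,19.95 ± 0.49,23.48 ± 0.87,21.30 ± 1.07,6.01 ± 0.20,13.22 ± 0.32,4.55 ± 0.66,"MS,RI,AC"
13,γ-Terpinene,monoterpene_hydrocarbon,no,1059,1060,0.61 ± 0.08,0.74 ± 0.10,-,-,0.24 ± 0.21,-,"MS,RI,AC"
14,Terpinolene,monoterpene_hydrocarbon,no,1088,1087,0.53 ± 0.04,0.65 ± 0.06,-,-,0.55 ± 0.08,-,"MS,RI,AC"
15,Linalool,monoterpene_alcohol,yes,1101,1099,-,1.58 ± 0.09,2.46 ± 0.18,0.29 ± 0.00,0.67 ± 0.07,0.96 ± 0.10,"MS,RI,AC"
16,Camphor,monoterpene_ketone,yes,1145,1143,6.72 ± 0.70,2.77 ± 0.18,26.80 ± 0.51,56.04 ± 1.47,31.86 ± 0.82,14.18 ± 0.70,"MS,RI,AC"
17,Borneol,monoterpene_alcohol,yes,1166,1166,2.59 ± 0.12,3.67 ± 0.46,0.69 ± 0.14,0.58 ± 0.10,4.03 ± 0.25,3.24 ± 0.35,"MS,RI,AC"
18,δ-Terpineol,monoterpene_alcohol,yes,1167,1166,-,-,0.45 ± 0.08,-,-,-,"MS,RI"
19,Isopinocamphone,monoterpene_ketone,yes,1174,1173,-,0.53 ± 0.22,0.45 ± 0.04,-,1.60 ± 0.14,0.78 ± 0.04,"MS,RI"
20,Terpinen-4-ol,monoterpene_alcohol,yes,1177,1174,1.19 ± 0.12,0.66 ± 0.59,1.46 ± 0.06,0.66 ± 0.07,1.04 ± 0.13,0.96 ± 0.05,"MS,RI,AC"
21,p-Cymen-8-ol,monoterpene_alcohol,yes,1187,1184,-,-,0.42 ± 0.02,-,-,-,"MS,RI"
22,α-Terpineol,monoterpene_alcohol,yes,1191,1189,1.71 ± 0.31,2.10 ± 0.27,6.61 ± 0.33,1.33 ± 0.07,1.56 ± 0.07,1.12 ± 0.10,"MS,RI,AC"
23,Myrtenol,monoterpene_alcohol,yes,1198,1195,-,0.40 ± 0.08,-,-,-,0.80 ± 0.04,"MS,RI"
24,trans-Piperitol,monoterpene_alcohol,yes,1205,1205,-,0.53 ± 0.06,-,3.02 ± 0.26,0.83 ± 0.07,1.08 ± 0.14,"MS,RI"
25,Verbenone,monoterpene_ketone,yes,1211,1206,3.64 ± 0.12,14.79 ± 0.57,3.46 ± 0.37,0.99 ± 0.08,4.93 ± 0.28,39.14 ± 0.55,"MS,RI,AC"
26,Carveol,monoterpene_alcohol,yes,1219,1219,-,-,-,0.45 ± 0.04,-,-,"MS,RI"
27,Geraniol,monoterpene_alcohol,yes,1256,1255,0.90 ± 0.13,3.59 ± 0.20,-,-,-,-,"MS,RI,AC"
28,Bornyl acetate,monoterpene_ester,yes,1288,1284,-,1.90 ± 0.10,-,-,13.92 ± 0.61,15.57 ± 1.61,"MS,RI,AC"
29,β-Caryophyllene,sesquiterpene,no,1421,1420,-,0.51 ± 0.06,-,-,-,-,"MS,RI,AC"
30,α-Bisabolol,sesquiterpene,yes,1686,1684,-,-,-,0.65 ± 0.23,-,-,"MS,RI,AC"
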