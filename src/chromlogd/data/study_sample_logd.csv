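compound_id,name,7.0,8.0,9.0,10.0
28,o-Phenylenediamine,0.38,0.38,0.07,0.28
29,m-Phenylenediamine,0.03,-0.02,-0.41,-0.15
30,2-Methyl-4-nitroaniline,1.67,1.63,1.31,1.60
31,"2,4-Dinitroaniline",1.71,1.69,1.58,1.64
32,2-Chloro-4-nitroaniline,1.99,1.96,1.93,1.92
33,"2-Chloro-4,6-dinitroaniline",2.11,2.07,1.99,1.97
34,"1,1'-Carbonyldiimidazole",-0.52,-0.46,-0.84,-0.89
35,Etiracetam,0.70,0.54,0.17,0.04
36,2-Amino-4-methyl-6-methoxy-s-triazine,1.28,1.22,0.94,0.86
37,Citrazinic acid,2.29,2.05,1.20,1.87
38,"2-Amino-1,3,5-triazine",1.27,1.22,0.95,0.88
39,4-Iodoaniline,2.14,2.10,2.13,2.08
40,Imidazole,-1.07,-0.50,-0.58,-0.50
41,4-Methylimidazole,-0.54,0.06,0.08,0.07
42,"3,3'-Sulfonyldianiline",1.70,1.67,1.20,0.69
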