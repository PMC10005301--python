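id,name,logP,pKa1,pKa2,role,A,B
1,2-Methylaniline,1.40,4.45,,model,,
2,4-Methylaniline,1.41,5.08,,model,,
3,"N,N-Diethylaniline",3.31,6.57,,model,,
4,4-Methylpyridine,1.33,5.99,,model,,
5,4-Fluoroaniline,1.15,4.65,,model,,
6,"2,6-Dimethylpyridine",1.68,6.65,,model,,
7,"2,4,6-Trimethylpyridine",2.01,7.43,,model,,
8,"N,N-Dimethylaniline",2.31,5.07,,model,,
9,Benzylamine,1.09,9.35,,model,,
10,4-Ethoxyaniline,1.24,5.25,,model,,
11,2-Methoxyaniline,0.95,4.53,,model,,
12,4-Methoxyaniline,0.80,5.36,,model,,
13,"1,4-Benzenediamine",-0.30,6.31,2.97,model,,
14,Pyridine,0.78,6.62,,model,,
15,"N,N-Dimethylbenzylamine",1.98,8.80,,model,,
16,2-Amino-4-methylpyridine,0.89,7.38,,model,,
17,4-Isopropylaniline,2.23,4.85,,model,,
18,"2,4-Dimethylpyridine",1.65,6.58,,model,,
19,"2,4-Dimethylaniline",1.68,4.70,,model,,
20,2-Amino-6-methylpyridine,1.08,7.41,,model,,
21,Aniline,0.90,4.60,,model,,
22,4-Phenylpyridine,2.59,5.45,,model,,
23,2-Picoline,1.09,5.94,,model,,
24,4-Bromoaniline,2.05,3.89,,verification,,
25,2-Ethylaniline,1.74,4.37,,verification,,
26,2-Ethylpyridine,1.67,5.97,,verification,,
27,Dibenzylamine,3.03,8.76,,verification,,
28,"1,2-Diaminobenzene",,,,sample,,
29,"1,3-Diaminobenzene",,,,sample,,
30,2-Methyl-4-nitroaniline,,,,sample,,
31,"2,4-Dinitroaniline",,,,sample,,
32,2-Chloro-4-nitroaniline,,,,sample,,
33,"2-Chloro-4,6-dinitroaniline",,,,sample,,
34,"1,1'-Carbonyldiimidazole",,,,sample,,
35,Etiracetam,,,,sample,,
36,2-Amino-4-methyl-6-methoxy-s-triazine,,,,sample,,
37,Citrazinic acid,,,,sample,,
38,"2-Amino-1,3,5-triazine",,,,sample,,
39,4-Iodoaniline,,,,sample,,
40,Imidazole,,,,sample,,
41,4-Methylimidazole,,,,sample,,
42,"3,3'-Sulfonyldianiline",,,,sample,,
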