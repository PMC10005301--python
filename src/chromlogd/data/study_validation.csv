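compound_id,name,pKa,logP,pH,literature_logD,determined_logD,error_pct
24,4-Bromoaniline,3.89,2.05,7.0,2.05,1.83,-10.73
24,4-Bromoaniline,3.89,2.05,8.0,2.05,1.81,-11.71
24,4-Bromoaniline,3.89,2.05,9.0,2.05,1.85,-9.76
24,4-Bromoaniline,3.89,2.05,10.0,2.05,1.81,-11.71
25,2-Ethylaniline,4.37,1.74,7.0,1.74,1.79,2.87
25,2-Ethylaniline,4.37,1.74,8.0,1.74,1.77,1.72
25,2-Ethylaniline,4.37,1.74,9.0,1.74,1.75,0.57
25,2-Ethylaniline,4.37,1.74,10.0,1.74,1.71,-1.72
26,2-Ethylpyridine,5.97,1.67,7.0,1.63,1.62,-0.61
26,2-Ethylpyridine,5.97,1.67,8.0,1.67,1.62,-2.99
26,2-Ethylpyridine,5.97,1.67,9.0,1.67,1.60,-4.19
26,2-Ethylpyridine,5.97,1.67,10.0,1.67,1.65,-1.20
27,Dibenzylamine,8.76,3.03,7.0,1.26,1.52,20.63
27,Dibenzylamine,8.76,3.03,8.0,2.20,2.36,7.27
27,Dibenzylamine,8.76,3.03,9.0,2.83,2.81,-0.71
27,Dibenzylamine,8.76,3.03,10.0,3.00,3.00,0.00
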