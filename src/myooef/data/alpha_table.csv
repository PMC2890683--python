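te_ms,compartment,alpha1,alpha2,alpha3
24,coronary_sinus,2.42,4.25,3.94
36,coronary_sinus,4.78,5.27,4.05
48,coronary_sinus,7.25,6.33,4.17
60,coronary_sinus,9.55,7.32,4.28
72,coronary_sinus,11.54,8.18,4.37
24,myocardium,2.52,2.69,2.83
36,myocardium,3.76,3.22,2.89
48,myocardium,4.57,3.57,2.93
60,myocardium,5.09,3.80,2.95
72,myocardium,5.45,3.95,2.97
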