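item,label,a,se_a,b1,se_b1,b2,se_b2,b3,se_b3
1,Sadness,2.38,0.06,1.10,0.05,2.75,0.12,3.13,0.15
2,Pessimism,2.20,0.05,1.12,0.05,2.57,0.09,3.35,0.16
3,Past failure,2.04,0.05,1.32,0.05,1.98,0.07,3.41,0.14
4,Loss of pleasure,2.27,0.05,0.95,0.05,2.34,0.08,3.25,0.15
5,Guilty feelings,1.72,0.04,0.75,0.03,2.96,0.08,3.78,0.13
6,Punishment feelings,1.74,0.05,1.46,0.05,2.39,0.07,2.63,0.07
7,Self-dislike,2.86,0.07,1.24,0.07,1.60,0.09,2.54,0.14
8,Self-criticalness,1.62,0.03,0.25,0.03,1.78,0.04,3.24,0.08
9,Suicidal thoughts,2.12,0.07,1.89,0.08,3.22,0.15,3.60,0.19
10,Crying,1.52,0.04,1.16,0.03,1.93,0.04,2.73,0.06
11,Agitation,1.59,0.04,0.83,0.03,2.90,0.06,3.19,0.08
12,Loss of interest,2.73,0.06,0.89,0.05,2.26,0.11,2.87,0.15
13,Indecisiveness,2.03,0.04,0.78,0.04,1.88,0.06,2.12,0.06
14,Worthlessness,3.31,0.09,1.31,0.10,1.80,0.12,2.72,0.20
15,Loss of energy,2.35,0.05,0.40,0.04,1.96,0.07,3.05,0.13
16,Changes in sleep,1.58,0.03,0.03,0.03,1.69,0.04,3.04,0.07
17,Irritability,2.13,0.04,0.65,0.04,2.10,0.07,2.93,0.11
18,Changes in appetite,1.40,0.03,0.48,0.03,2.31,0.04,3.28,0.07
19,Concentration difficulty,2.07,0.04,0.57,0.03,1.60,0.05,2.84,0.09
20,Tiredness or fatigue,2.24,0.04,0.32,0.03,1.75,0.06,2.52,0.09
21,Loss of interest in sex,1.32,0.04,1.91,0.04,3.26,0.07,4.44,0.12
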