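trait,mean,sd,cv,shannon,kind
Days to heading,102.95,10.543,10.24,1.91,integer
Plant height,112.766,14.994,13.30,2.05,continuous
Leaf length,38.6727,7.51025,19.42,1.89,continuous
Leaf width,2.0423,0.33795,16.55,2.08,continuous
Valid spikes per plant,7.74,2.007,25.83,2.03,continuous
Spike length,25.07,2.593,10.34,2.02,continuous
Kernel numbers per spike,174.42,52.668,30.20,1.92,continuous
Grain number,159.68,49.365,30.91,1.92,continuous
1000-seed weight,26.75,4.129,15.44,2.06,continuous
Brown rice rate,78.76,2.414,3.07,1.79,percent
Milled rice rate,58.80,4.439,7.59,2.04,percent
Head rice rate,53.61,8.955,16.70,1.89,percent
Chalky rice rate,32.17,31.064,96.56,1.68,percent
Chalkiness,11.97,16.455,137.43,1.55,percent
Length-width ratio,2.39,0.293,12.26,1.96,continuous
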