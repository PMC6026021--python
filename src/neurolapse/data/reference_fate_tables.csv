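study,condition,total_tracked,tracked_a,a_to_a,a_to_b,a_to_c,tracked_b,b_to_a,b_to_b,b_to_c
addback_day6_14,TF+,110.9,83.33,62.27,2.267,18.80,27.57,9.533,3.300,14.73
addback_day6_14,addback_day6,93.60,58.33,40.17,2.033,16.13,35.27,10.43,3.167,21.67
addback_day6_14,addback_day7,97.97,46.92,26.56,1.333,19.03,44.67,33.90,2.100,21.27
addback_day6_14,addback_day8,110.3,57.27,33.90,2.100,21.27,55.54,25.83,5.600,24.43
addback_day6_14,TF-,101.6,55.87,25.83,5.600,24.43,45.73,5.267,10.70,29.77
soma_protective_day0_14,TF+,86.20,42.47,27.47,0.6000,14.40,43.73,14.87,1.733,27.13
soma_protective_day0_14,TF+_drug5,80.27,41.07,27.60,0.7333,12.73,39.20,17.00,2.333,19.87
soma_protective_day0_14,TF-_drug2.5,98.27,42.80,21.40,2.400,19.00,55.47,15.07,7.000,33.40
soma_protective_day0_14,TF-_drug5,96.87,38.27,18.67,1.867,17.73,58.60,11.80,7.200,39.60
soma_protective_day0_14,TF-,92.53,42.47,11.13,4.467,26.87,50.07,6.867,4.333,38.87
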