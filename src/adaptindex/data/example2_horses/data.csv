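group_id,parameter,state,mean,sd,n
g1,P95,F1,375,14,6
g1,P95,F2,393,20,6
g1,P95,F3,380,16,6
g1,P50,F1,170,5,6
g1,P50,F2,185,3,6
g1,P50,F3,176,19,6
g1,hemoglobin,F1,16.5,0.2,6
g1,hemoglobin,F2,16.9,0.7,6
g1,hemoglobin,F3,16.5,0.2,6
g1,heart_rate,F1,37.0,1.5,6
g1,heart_rate,F2,112.9,2.7,6
g1,heart_rate,F3,39.0,2.9,6
g1,lactate,F1,50.2,28.9,6
g1,lactate,F2,55.5,14.9,6
g1,lactate,F3,50.8,7.1,6
g1,reserve_alkalinity,F1,550,19,6
g1,reserve_alkalinity,F2,550,26,6
g1,reserve_alkalinity,F3,560,20,6
g2,P95,F1,330,11,6
g2,P95,F2,333,9,6
g2,P95,F3,325,7,6
g2,P50,F1,163,5,6
g2,P50,F2,166,4,6
g2,P50,F3,161,3,6
g2,hemoglobin,F1,15.1,0.2,6
g2,hemoglobin,F2,16.0,0.5,6
g2,hemoglobin,F3,15.3,0.5,6
g2,heart_rate,F1,42.5,3.2,6
g2,heart_rate,F2,129.2,2.9,6
g2,heart_rate,F3,45.0,6.1,6
g2,lactate,F1,59.0,29.9,6
g2,lactate,F2,92.3,13.5,6
g2,lactate,F3,64.2,19.0,6
g2,reserve_alkalinity,F1,475,22,6
g2,reserve_alkalinity,F2,430,22,6
g2,reserve_alkalinity,F3,465,11,6
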