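group_id,parameter,state,mean,sd,n
B,hexokinase,F1,13.8,1.2,10
B,hexokinase,F2,7.1,1.7,10
B,ammonia,F1,103,11,10
B,ammonia,F2,186,48,10
B,11-HCS,F1,13.1,2.9,10
B,11-HCS,F2,30.8,6.8,10
B,glycogen,F1,702,215,10
B,glycogen,F2,293,218,10
B,lactate,F1,6.1,2.0,10
B,lactate,F2,16.6,8.5,10
C,hexokinase,F1,13.4,1.7,8
C,hexokinase,F2,12.7,2.0,9
C,ammonia,F1,83,18,8
C,ammonia,F2,127,73,9
C,11-HCS,F1,8.1,2.9,8
C,11-HCS,F2,30.2,5.7,9
C,glycogen,F1,897,269,8
C,glycogen,F2,451,147,9
C,lactate,F1,5.5,0.8,8
C,lactate,F2,7.2,1.4,9
D,hexokinase,F1,14.2,1.1,9
D,hexokinase,F2,5.5,2.3,9
D,ammonia,F1,79,13,9
D,ammonia,F2,110,34,9
D,11-HCS,F1,8.9,1.2,9
D,11-HCS,F2,31.9,2.6,9
D,glycogen,F1,745,173,9
D,glycogen,F2,225,124,9
D,lactate,F1,5.2,1.1,9
D,lactate,F2,12.5,6.2,9
E,hexokinase,F1,13.1,2.8,8
E,hexokinase,F2,8.6,1.4,8
E,ammonia,F1,73,18,8
E,ammonia,F2,112,51,8
E,11-HCS,F1,10.9,1.5,8
E,11-HCS,F2,28.8,2.5,8
E,glycogen,F1,757,165,8
E,glycogen,F2,387,153,8
E,lactate,F1,5.5,1.1,8
E,lactate,F2,9.8,7.4,8
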