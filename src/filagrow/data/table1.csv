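group,day,mean_increment,sd_increment
0-50,7,0.3,0.4
0-50,14,1,0.7
0-50,21,0.5,0.5
0-50,28,0.3,0.4
50-100,7,3.5,1.9
50-100,14,3.5,2.5
50-100,21,1.7,1.2
50-100,28,1,0.8
100-150,7,7.7,1.9
100-150,14,3,0.8
100-150,21,1.3,0.5
100-150,28,1.5,0.5
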