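group,day,mean_cells,sd_cells,length_um
0-50,0,27.7,1.3,50.0
0-50,7,28.0,1.2,50.5
0-50,14,29.0,1.3,52.1
0-50,21,29.6,1.3,53.2
0-50,28,29.95,1.4,53.9
50-100,0,69.3,9.7,124.7
50-100,7,72.7,10.4,130.9
50-100,14,76.2,11.4,137.2
50-100,21,77.8,11.8,140.1
50-100,28,83.1,12.0,149.6
100-150,0,111.6,1.0,200.9
100-150,7,119.3,2.7,214.8
100-150,14,122.2,3.4,220.0
100-150,21,123.4,2.8,222.1
100-150,28,123.2,2.7,221.8
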