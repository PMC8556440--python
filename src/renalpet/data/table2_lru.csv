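patient_id,median_lru,sd_lru,range_min,range_max,delta_max
1,46.7,1.1,44.6,48.5,4.0
2,46.3,2.2,43.8,51.2,7.3
3,54.8,0.6,53.5,55.4,1.9
4,48.3,0.8,46.9,49.8,2.9
5,47.7,0.5,46.9,48.6,1.8
6,51.1,1.1,48.1,52.1,4.0
7,51.1,0.6,49.8,52.6,2.8
8,5.8,1.6,4.9,11.0,6.1
9,47.3,0.7,46.3,48.9,2.6
10,48.9,0.8,47.8,50.5,2.7
11,51.6,0.6,50.4,52.7,2.3
12,46.6,0.5,45.6,47.6,1.9
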