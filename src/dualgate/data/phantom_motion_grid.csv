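n_card,1,2,3,4,5,6
1,0.0,7.5,10.4,10.6,11.1,12.0
4,3.0,9.3,11.2,12.5,12.7,12.8
6,3.1,9.3,11.3,12.5,12.8,12.9
8,3.5,9.4,11.8,12.6,12.8,12.9
10,3.5,9.4,11.8,12.6,12.8,12.9
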