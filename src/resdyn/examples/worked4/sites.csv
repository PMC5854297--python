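site_id,cost,mu,perimeter,h_1
1,1.0,0.5,4.0,6.0
2,1.0,0.5,4.0,2.0
3,1.0,0.5,4.0,4.0
4,1.0,0.5,4.0,3.0
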