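donor,level,hu,hu_screw_side,t_over_l
1,L3,118,93,0.17
3,L1,303,343,0.35
4,L4,62,58,0.13
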