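donor,age_years,sex,t_score,bone_quality,printed
1,97,female,-2.4,osteopenia,1
2,79,female,-3.2,osteoporosis,0
3,81,male,0.8,normal,1
4,95,male,-3.2,osteoporosis,1
5,78,male,1.1,normal,0
6,91,male,-3.4,osteoporosis,0
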