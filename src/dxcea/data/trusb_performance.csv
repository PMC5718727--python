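trusb_type,histology_definition,subgroup,p_nc,p_noncs,p_cs
1,1,low_risk,0.65,0.35,0.00
1,1,intermediate_risk,0.24,0.42,0.34
1,1,high_risk,0.00,0.00,1.00
1,2,low_risk,0.65,0.35,0.00
1,2,intermediate_risk,0.24,0.17,0.59
1,2,high_risk,0.00,0.00,1.00
2,1,low_risk,0.55,0.45,0.00
2,1,intermediate_risk,0.55,0.25,0.20
2,1,high_risk,0.55,0.00,0.45
2,2,low_risk,0.55,0.45,0.00
2,2,intermediate_risk,0.55,0.10,0.35
2,2,high_risk,0.55,0.00,0.45
3,1,low_risk,0.00,1.00,0.00
3,1,intermediate_risk,0.00,0.75,0.25
3,1,high_risk,0.00,0.75,0.25
3,2,low_risk,0.00,1.00,0.00
3,2,intermediate_risk,0.00,0.75,0.25
3,2,high_risk,0.00,0.75,0.25
4,1,low_risk,0.80,0.20,0.00
4,1,intermediate_risk,0.20,0.37,0.43
4,1,high_risk,0.00,0.00,1.00
4,2,low_risk,0.79,0.21,0.00
4,2,intermediate_risk,0.15,0.11,0.74
4,2,high_risk,0.00,0.00,1.00
5,1,low_risk,0.68,0.32,0.00
5,1,intermediate_risk,0.05,0.08,0.87
5,1,high_risk,0.05,0.08,0.87
5,2,low_risk,0.68,0.32,0.00
5,2,intermediate_risk,0.05,0.08,0.87
5,2,high_risk,0.05,0.08,0.87
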