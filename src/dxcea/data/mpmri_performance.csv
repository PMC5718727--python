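mpmri_cutoff,mpmri_definition,subgroup,p_nc,p_noncs,p_cs
2,1,no_cancer,0.00,0.23,0.77
2,1,low_risk,0.00,0.20,0.80
2,1,intermediate_risk,0.01,0.06,0.93
2,1,high_risk,0.00,0.00,1.00
2,2,no_cancer,0.00,0.07,0.93
2,2,low_risk,0.00,0.08,0.92
2,2,intermediate_risk,0.01,0.01,0.98
2,2,high_risk,0.00,0.00,1.00
3,1,no_cancer,0.33,0.41,0.26
3,1,low_risk,0.28,0.40,0.32
3,1,intermediate_risk,0.08,0.18,0.74
3,1,high_risk,0.00,0.00,1.00
3,2,no_cancer,0.33,0.17,0.50
3,2,low_risk,0.28,0.16,0.56
3,2,intermediate_risk,0.08,0.05,0.87
3,2,high_risk,0.00,0.00,1.00
4,1,no_cancer,0.86,0.08,0.06
4,1,low_risk,0.75,0.14,0.11
4,1,intermediate_risk,0.30,0.24,0.46
4,1,high_risk,0.00,0.06,0.94
4,2,no_cancer,0.86,0.03,0.11
4,2,low_risk,0.75,0.04,0.21
4,2,intermediate_risk,0.30,0.04,0.65
4,2,high_risk,0.00,0.00,1.00
5,1,no_cancer,0.96,0.02,0.02
5,1,low_risk,0.98,0.01,0.01
5,1,intermediate_risk,0.60,0.17,0.23
5,1,high_risk,0.23,0.16,0.61
5,2,no_cancer,0.96,0.01,0.03
5,2,low_risk,0.98,0.00,0.02
5,2,intermediate_risk,0.60,0.03,0.38
5,2,high_risk,0.23,0.00,0.77
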