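bad_breath,bleeding_gums,breed_risk_group,clinical_signs,p_false,p_true
False,False,Low,Bad,0.625,0.375
False,False,Low,Medium,0.523,0.478
False,False,Low,Good,0.970,0.030
False,False,Expected,Bad,0.600,0.400
False,False,Expected,Medium,0.473,0.528
False,False,Expected,Good,0.945,0.055
False,False,High,Bad,0.425,0.575
False,False,High,Medium,0.375,0.625
False,False,High,Good,0.750,0.250
False,True,Low,Bad,0.525,0.475
False,True,Low,Medium,0.463,0.538
False,True,Low,Good,0.875,0.125
False,True,Expected,Bad,0.500,0.500
False,True,Expected,Medium,0.413,0.588
False,True,Expected,Good,0.850,0.150
False,True,High,Bad,0.275,0.725
False,True,High,Medium,0.275,0.725
False,True,High,Good,0.675,0.325
True,False,Low,Bad,0.525,0.475
True,False,Low,Medium,0.480,0.520
True,False,Low,Good,0.935,0.065
True,False,Expected,Bad,0.500,0.500
True,False,Expected,Medium,0.430,0.570
True,False,Expected,Good,0.910,0.090
True,False,High,Bad,0.300,0.700
True,False,High,Medium,0.313,0.688
True,False,High,Good,0.675,0.325
True,True,Low,Bad,0.450,0.550
True,True,Low,Medium,0.388,0.613
True,True,Low,Good,0.800,0.200
True,True,Expected,Bad,0.425,0.575
True,True,Expected,Medium,0.343,0.658
True,True,Expected,Good,0.775,0.225
True,True,High,Bad,0.175,0.825
True,True,High,Medium,0.193,0.808
True,True,High,Good,0.600,0.400
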