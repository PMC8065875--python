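class_id,name,S0,T10_s,T2star0_s,vP,PS_per_min,enhancement_mode,curve_params
1,csf,12000,4.00,0.20,0.0,0.0,none,{}
2,nawm,9726,0.99,0.06,0.0057,0.000275,patlak,{}
3,wmh,9402,1.20,0.06,0.0072,0.000391,patlak,{}
4,stroke,9858,1.27,0.06,0.0105,0.000725,patlak,{}
5,cortical_gm,9298,1.34,0.06,0.0120,0.000385,patlak,{}
6,deep_gm,9298,1.34,0.06,0.0120,0.000385,patlak,{}
7,meninges,9000,1.00,0.05,0.0,0.0,extracerebral_curve,"{""form"": ""exponential"", ""a"": 2.0, ""tau_s"": 180.0}"
8,muscle,9000,1.00,0.035,0.0,0.0,extracerebral_curve,"{""form"": ""exponential"", ""a"": 1.5, ""tau_s"": 300.0}"
9,mandible_vertebrae,2000,0.50,0.010,0.0,0.0,extracerebral_curve,"{""form"": ""exponential"", ""a"": 0.5, ""tau_s"": 400.0}"
10,skull_diploe,10500,0.35,0.030,0.0,0.0,extracerebral_curve,"{""form"": ""exponential"", ""a"": 0.8, ""tau_s"": 300.0}"
11,skull_inner_table,1500,0.50,0.010,0.0,0.0,extracerebral_curve,"{""form"": ""exponential"", ""a"": 0.2, ""tau_s"": 400.0}"
12,skull_outer_table,1500,0.50,0.010,0.0,0.0,extracerebral_curve,"{""form"": ""exponential"", ""a"": 0.2, ""tau_s"": 400.0}"
13,vessels,10000,1.44,0.05,0.55,0.0,patlak,{}
14,skin,9500,0.85,0.040,0.0,0.0,extracerebral_curve,"{""form"": ""power"", ""a"": 1.2, ""tref_s"": 600.0, ""b"": 0.4}"
15,adipose,11000,0.30,0.05,0.0,0.0,none,{}
16,eyes,11000,3.00,0.15,0.0,0.0,extracerebral_curve,"{""form"": ""power"", ""a"": 0.15, ""tref_s"": 600.0, ""b"": 0.5}"
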