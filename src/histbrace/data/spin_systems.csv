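label,g1,g2,g3,absA1,absA2,absA3,signs,shf_values,shf_isotope,g_strain,A_strain,lw_gauss,lw_lorentz,freq_GHz,isotope
free_X_14N,2.027,2.095,2.261,255,110,336,"+,+,-","43,43,28",14N,"0,0.02,0.007","130,55,160",0.6,0.6,9.3046,63Cu
free_X_15N,2.029,2.081,2.261,255,115,336,"+,+,-","60,60,40",15N,"0,0.025,0.005","160,60,160",0.6,0.6,9.2973,63Cu
free_Q_15N,2.032,2.112,2.260,255,115,340,"+,+,-","60,60,40",15N,"0,0.045,0.007","20,10,120",4.5,4.5,35.00,63Cu
chitin_X_14N,2.042,2.053,2.205,80,85,620,"unknown,-,-","40,40,32",14N,"0.004,0,0.007","20,20,20",0.4,0.4,9.2988,63Cu
chitin_X_15N,2.038,2.046,2.209,88,95,610,"unknown,-,-","56,56,45",15N,"0.005,0,0.009","10,10,10",0.5,0.6,9.2884,63Cu
chitin_Q_15N,2.046,2.057,2.208,80,90,610,"unknown,-,-","55,55,45",15N,"0.005,0,0.003","90,40,240",1.3,1.3,35.05,63Cu
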