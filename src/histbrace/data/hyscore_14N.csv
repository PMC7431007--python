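sample,label,aiso,T,euler1,euler2,euler3,K,eta,qeuler1,qeuler2,qeuler3,isotope
free,N(A),1.6,0.3,10,100,60,1.75,0.7,60,10,95,14N
free,N(B),1.3,0.25,0,94,20,1.40,0.85,20,0,-95,14N
chitin,N(A),1.55,0.35,10,110,60,1.35,0.9,60,30,95,14N
chitin,N(B),1.25,0.30,120,70,0,1.40,0.8,10,-10,-80,14N
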