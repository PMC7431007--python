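sample,label,orientation,aiso,T,euler1,euler2,euler3,isotope
free,N(A),perpendicular,2.40,0.34,10,100,60,15N
free,N(B),perpendicular,2.00,0.30,0,94,20,15N
free,N(A),parallel,2.40,0.34,10,100,60,15N
free,N(B),parallel,2.00,0.30,0,94,20,15N
chitin,N(A),perpendicular,2.20,0.40,10,110,60,15N
chitin,N(B),perpendicular,1.90,0.35,120,70,0,15N
chitin,N(A),parallel,2.25,0.40,10,110,60,15N
chitin,N(B),parallel,1.85,0.35,120,60,0,15N
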