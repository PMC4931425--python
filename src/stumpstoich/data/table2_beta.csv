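mass_ratio,C,N,S,P,K,Na,Ca,Mg,Fe,Zn,Mn,Cu,erg
0.90,0.8,10.3,0.9,37.3,5.7,2.6,1.9,2.2,7.0,1.8,1.6,6.5,28.8
0.58,0.5,6.6,0.6,24.0,3.7,1.7,1.2,1.4,4.5,1.1,1.0,4.2,18.6
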