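N,P,K,Na,Ca,Mg,Fe,Zn,Mn,Cu
13.3,48.1,7.3,3.4,2.5,2.8,9.1,2.3,2.1,8.4
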