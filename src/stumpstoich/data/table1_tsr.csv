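species,sex,group,N,P,K,Na,Ca,Mg,Fe,Zn,Mn,Cu
S_rubra,female,low,258.6,1772.9,70.6,133.5,2.6,15.9,11.0,11.6,0.7,78.7
S_rubra,female,high,19.5,36.9,9.7,39.8,1.0,5.7,1.2,5.1,0.4,9.3
A_rusticus,female,low,133.3,1252.1,54.8,104.7,1.6,12.9,6.2,12.6,0.5,68.5
A_rusticus,female,high,10.0,26.1,7.5,31.2,0.7,4.6,0.7,5.5,0.2,8.1
C_mariana,female,low,207.5,1790.2,89.0,85.2,2.1,25.4,2.8,8.0,0.8,12.2
C_mariana,female,high,15.6,37.3,12.2,25.4,0.9,9.1,0.3,3.5,0.4,1.5
S_rubra,male,low,206.3,1052.2,54.6,101.5,2.1,13.8,3.9,10.7,0.8,30.7
S_rubra,male,high,15.5,21.9,7.5,30.3,0.8,4.9,0.4,4.7,0.4,3.6
A_rusticus,male,low,177.6,1458.0,72.9,90.7,1.7,20.3,3.3,7.5,0.9,11.7
A_rusticus,male,high,13.4,30.3,10.0,27.1,0.7,7.3,0.4,3.3,0.4,1.4
C_mariana,male,low,244.4,1669.5,70.3,176.2,1.9,18.3,4.1,8.7,0.7,15.2
C_mariana,male,high,18.4,34.7,9.6,52.6,0.8,6.6,0.5,3.8,0.3,1.8
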