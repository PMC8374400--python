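Sample,Bennettitales,Cheirolepidiaceae,Corystospermales,Cyatheales
HJG 01,33.8,1.5,25,6.6
HJG 02,8.9,9.1,34,4.7
HJG 03,12.1,29.1,30.4,2.7
HJG 04,9.1,7.2,45,1.9
HJG 05,8.6,2.9,34.3,4.8
HJG 06,15.1,5.7,34,3.8
HJG 07,4.2,9.8,50,0
HJG 08,6.9,0.9,63.8,0
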