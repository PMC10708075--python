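compound,vip,gini,xa_printed
(E)-2-hexenal,1.52633,0.69,1.00
ethyl caprylate,1.50715,0.65,0.96
β-ocimene,1.22437,0.33,0.62
ethyl butanoate,1.12642,0.64,0.82
styrene,0.945676,0.25,0.46
(3Z)-3-hexen-1-yl acetate,0.92031,0.08,0.33
methyl salicylate,0.908079,0.34,0.52
ethyl hexanoate,0.905574,0.08,0.32
nonanal,0.760134,0.19,0.35
α-ionone,0.628868,0.02,0.18
caryophyllene,0.502894,0.18,0.25
2-nonanol,0.137078,0.06,0.03
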