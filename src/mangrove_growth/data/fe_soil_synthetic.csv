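site,region,position,compartment,metal,conc
NP1,CanGio,upstream,soil,Fe,24619.7
DK4,CanGio,upstream,soil,Fe,17986.0
DK6,CanGio,upstream,soil,Fe,26744.6
DK7,CanGio,upstream,soil,Fe,28454.4
DK8,CanGio,upstream,soil,Fe,30329.7
NP2,CanGio,downstream,soil,Fe,24427.3
DN1,ThiVai,upstream,soil,Fe,55475.6
DN2,ThiVai,upstream,soil,Fe,40281.5
M5,ThiVai,upstream,soil,Fe,34619.1
M3,ThiVai,upstream,soil,Fe,32942.6
M1,ThiVai,downstream,soil,Fe,22190.7
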