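site,region,position,compartment,metal,conc
NP1,CanGio,upstream,soil,Cu,80.04
NP1,CanGio,upstream,soil,Cr,4.96
NP1,CanGio,upstream,soil,Ni,3.31
NP1,CanGio,upstream,root,Cu,0.21
NP1,CanGio,upstream,root,Cr,1.06
NP1,CanGio,upstream,root,Ni,0.57
NP1,CanGio,upstream,leaf,Cu,0.31
NP1,CanGio,upstream,leaf,Cr,1.51
NP1,CanGio,upstream,leaf,Ni,0.71
DK4,CanGio,upstream,soil,Cu,70.82
DK4,CanGio,upstream,soil,Cr,3.76
DK4,CanGio,upstream,soil,Ni,2.72
DK4,CanGio,upstream,root,Cu,0.6
DK4,CanGio,upstream,root,Cr,0.7
DK4,CanGio,upstream,root,Ni,0.45
DK4,CanGio,upstream,leaf,Cu,0.72
DK4,CanGio,upstream,leaf,Cr,0.37
DK4,CanGio,upstream,leaf,Ni,0.12
DK6,CanGio,upstream,soil,Cu,64.51
DK6,CanGio,upstream,soil,Cr,4.35
DK6,CanGio,upstream,soil,Ni,2.63
DK6,CanGio,upstream,root,Cu,0.31
DK6,CanGio,upstream,root,Cr,0.32
DK6,CanGio,upstream,root,Ni,0.11
DK6,CanGio,upstream,leaf,Cu,0.25
DK6,CanGio,upstream,leaf,Cr,0.29
DK6,CanGio,upstream,leaf,Ni,0.01
DK7,CanGio,upstream,soil,Cu,65.65
DK7,CanGio,upstream,soil,Cr,4.44
DK7,CanGio,upstream,soil,Ni,3.08
DK7,CanGio,upstream,root,Cu,0.54
DK7,CanGio,upstream,root,Cr,0.26
DK7,CanGio,upstream,root,Ni,0.17
DK7,CanGio,upstream,leaf,Cu,0.39
DK7,CanGio,upstream,leaf,Cr,0.4
DK7,CanGio,upstream,leaf,Ni,0.09
DK8,CanGio,upstream,soil,Cu,75.76
DK8,CanGio,upstream,soil,Cr,4.28
DK8,CanGio,upstream,soil,Ni,3.25
DK8,CanGio,upstream,root,Cu,0.37
DK8,CanGio,upstream,root,Cr,1.2
DK8,CanGio,upstream,root,Ni,0.66
DK8,CanGio,upstream,leaf,Cu,0.18
DK8,CanGio,upstream,leaf,Cr,0.23
DK8,CanGio,upstream,leaf,Ni,0.01
NP2,CanGio,downstream,soil,Cu,76.62
NP2,CanGio,downstream,soil,Cr,4.49
NP2,CanGio,downstream,soil,Ni,3.06
NP2,CanGio,downstream,root,Cu,0.47
NP2,CanGio,downstream,root,Cr,0.32
NP2,CanGio,downstream,root,Ni,0.22
NP2,CanGio,downstream,leaf,Cu,0.36
NP2,CanGio,downstream,leaf,Cr,1.27
NP2,CanGio,downstream,leaf,Ni,0.46
DN1,ThiVai,upstream,soil,Cu,62.41
DN1,ThiVai,upstream,soil,Cr,12.39
DN1,ThiVai,upstream,soil,Ni,8.49
DN1,ThiVai,upstream,root,Cu,3.07
DN1,ThiVai,upstream,root,Cr,4.46
DN1,ThiVai,upstream,root,Ni,4.9
DN1,ThiVai,upstream,leaf,Cu,3.53
DN1,ThiVai,upstream,leaf,Cr,0.39
DN1,ThiVai,upstream,leaf,Ni,0.14
DN2,ThiVai,upstream,soil,Cu,134.03
DN2,ThiVai,upstream,soil,Cr,19.84
DN2,ThiVai,upstream,soil,Ni,11.35
DN2,ThiVai,upstream,root,Cu,8.17
DN2,ThiVai,upstream,root,Cr,11.69
DN2,ThiVai,upstream,root,Ni,8.54
DN2,ThiVai,upstream,leaf,Cu,2.12
DN2,ThiVai,upstream,leaf,Cr,0.49
DN2,ThiVai,upstream,leaf,Ni,0.01
M5,ThiVai,upstream,soil,Cu,60.4
M5,ThiVai,upstream,soil,Cr,21.14
M5,ThiVai,upstream,soil,Ni,12.01
M5,ThiVai,upstream,root,Cu,5.55
M5,ThiVai,upstream,root,Cr,2.19
M5,ThiVai,upstream,root,Ni,2.19
M5,ThiVai,upstream,leaf,Cu,4.03
M5,ThiVai,upstream,leaf,Cr,1.04
M5,ThiVai,upstream,leaf,Ni,0.27
M3,ThiVai,upstream,soil,Cu,79.46
M3,ThiVai,upstream,soil,Cr,13.62
M3,ThiVai,upstream,soil,Ni,8.82
M3,ThiVai,upstream,root,Cu,4.88
M3,ThiVai,upstream,root,Cr,1.52
M3,ThiVai,upstream,root,Ni,1.3
M3,ThiVai,upstream,leaf,Cu,3.4
M3,ThiVai,upstream,leaf,Cr,2.05
M3,ThiVai,upstream,leaf,Ni,1.82
M1,ThiVai,downstream,soil,Cu,82.51
M1,ThiVai,downstream,soil,Cr,14.75
M1,ThiVai,downstream,soil,Ni,5.82
M1,ThiVai,downstream,root,Cu,3.56
M1,ThiVai,downstream,root,Cr,5.24
M1,ThiVai,downstream,root,Ni,3.08
M1,ThiVai,downstream,leaf,Cu,7.83
M1,ThiVai,downstream,leaf,Cr,1.08
M1,ThiVai,downstream,leaf,Ni,0.76
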