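plot_id,region,position,mean_dbh,mean_height,density,age,salinity,G_reported,EF_Cu,EF_Cr,EF_Ni
NP1,CanGio,upstream,18.62,1989.97,26,26,8.0,390.53,3.41,0.11,0.09
DK4,CanGio,upstream,10.46,1232.91,42,32,12.4,277.08,4.13,0.11,0.1
DK6,CanGio,upstream,22.29,2293.78,8,38,12.9,275.46,2.53,0.09,0.07
DK7,CanGio,upstream,15.06,1673.72,13,37,15.5,201.61,2.42,0.08,0.08
DK8,CanGio,upstream,19.71,2082.55,11,40,15.5,197.74,2.62,0.07,0.07
NP2,CanGio,downstream,13.14,1501.13,16,39,18.2,166.91,3.29,0.1,0.09
DN1,ThiVai,upstream,16.13,1770.92,13,25,8.0,332.13,1.18,0.12,0.11
DN2,ThiVai,upstream,16.16,1757.51,20,25,9.6,331.82,3.49,0.26,0.2
M5,ThiVai,upstream,13.99,1574.53,11,31,11.3,317.36,1.83,0.32,0.24
M3,ThiVai,upstream,11.97,1381.85,20,23,13.5,300.98,2.53,0.22,0.19
M1,ThiVai,downstream,12.45,1428.23,17,32,17.1,152.97,3.9,0.35,0.18
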