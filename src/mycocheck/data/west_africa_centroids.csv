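country,lat,lon
BJ,9.5,2.3
BF,12.3,-1.7
GM,13.45,-15.4
GH,7.95,-1.0
GN,10.4,-11.0
GW,12.0,-15.0
CI,7.6,-5.6
LR,6.45,-9.3
ML,17.35,-3.5
NE,17.6,8.1
NG,9.1,8.1
SN,14.4,-14.5
SL,8.5,-11.8
TG,8.6,0.8
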