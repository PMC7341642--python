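area,country,plant_species,records,fungal_species,publications,chao,chao_se,bootstrap,bootstrap_se
West Africa,ALL,7072,16222,4843,860,7485,1445,900,151
Benin,BJ,2807,902,432,92,923,85,543,31
Burkina Faso,BF,2080,214,131,60,225,28,166,19
Gambia,GM,1760,137,118,24,481,122,157,21
Ghana,GH,2971,4121,1511,236,1798,33,1785,175
Guinea,GN,2923,1348,824,159,1957,138,1056,68
Guinea-Bissau,GW,1507,20,19,8,161,157,25,5
Ivory Coast,CI,3853,1736,1146,233,2958,184,1488,89
Liberia,LR,2403,184,159,68,999,282,213,24
Mali,ML,1739,140,103,34,258,52,134,14
Niger,NE,1218,123,85,30,169,30,109,13
Nigeria,NG,3378,2449,1273,281,2376,106,1613,69
Senegal,SN,2300,499,277,90,511,48,350,28
Sierra Leone,SL,1883,3564,1595,244,2307,66,1966,102
Togo,TG,3134,785,517,107,1310,123,665,64
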