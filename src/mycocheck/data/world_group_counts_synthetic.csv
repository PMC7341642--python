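group,species_worldwide
Agaricales,18000
Asterinales,1300
Capnodiales,7000
Chytridiomycota,1000
Erysiphales,1400
Eurotiales,1400
Helotiales,5500
Laboulbeniales,2200
Meliolales,2485
Mycetozoa,1000
Oomycota,1200
Pezizales,3500
Phallales,300
Polyporales,4000
Pucciniales,8000
Russulales,3175
Ustilaginales,1700
Xylariales,5500
Zygomycota,1100
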