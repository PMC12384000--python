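>Tau-R2 start=287 Tau 2N4R R2-repeat CaMBD
VQSKCGSKDNIKHVPGGG
>CaMKIIA start=296 CaMKII alpha CaMBD
RRKLKGAILTTMLATR
>GSK3B-CaMBD1 start=81 GSK3 beta CaMBD1
LVAIKKVLQDKRFKNRELQI
>GSK3B-CaMBD2 start=134 GSK3 beta CaMBD2
YVPETVYRVARHYSRAKQTLPVIY
>GSK3B-CaMBD3 start=193 GSK3 beta CaMBD3
TAVLKLCDFGSAKQLVRGEPNV
>Cdk5-CaMBD1 start=17 Cdk5 CaMBD1
GTVFKAKNRETHEIVALKRVALKRV
>Cdk5-CaMBD2 start=133 Cdk5 CaMBD2
LINRNGELKLADFGLARAFG
>ROCK1-CaMBD1 start=86 ROCK1 CaMBD1
AFGEVQLVRHKSTRKVYAM
>ROCK1-CaMBD2 start=1133 ROCK1 CaMBD2
IKRYGWKKQYVVVSSKKIL
>CN-CaMBD start=391 calcineurin A-subunit CaMBD
ARKEVIRNKIRAIGKMARVFSVLR
>TGM2-CaMBD1 start=414 transglutaminase 2 CaMBD1
KSINRSLIVGLKISTKSVGR
>TGM2-CaMBD2 start=665 transglutaminase 2 CaMBD2
VVNFESDKLKAVKGFRNVII
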