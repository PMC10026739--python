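id,name,layer_order,segment,rct_m2KW,ret_m2PaW
balaclava,Fleece balaclava,1,head,0.08,10.774410774410775
hat,Insulated hat,2,head,0.1,15.15151515151515
shirt_mid,Midweight cold weather shirt,1,trunk,0.12,16.16161616161616
shirt_mid,Midweight cold weather shirt,1,arms,0.06,8.08080808080808
drawers_mid,Midweight cold weather drawers,1,legs,0.08,10.774410774410775
fleece_jacket,Fleece jacket,2,trunk,0.22,31.746031746031743
fleece_jacket,Fleece jacket,2,arms,0.09,12.987012987012985
wind_jacket,Wind jacket,3,trunk,0.142,28.68686868686868
wind_jacket,Wind jacket,3,arms,0.05,10.1010101010101
pants_shell,Cold weather pants,2,legs,0.1,17.31601731601732
boots_icw,Intermediate cold wet boots,1,feet,0.35,84.84848484848484
acu_uniform,Combat uniform with patrol cap,2,head,0.06,9.09090909090909
acu_uniform,Combat uniform with patrol cap,2,trunk,0.15,22.727272727272723
acu_uniform,Combat uniform with patrol cap,2,arms,0.12,18.18181818181818
acu_uniform,Combat uniform with patrol cap,2,legs,0.13,19.696969696969695
glove_liner,Glove liner,1,hands,0.06,8.08080808080808
glove_insulated,Insulated glove,2,hands,0.16,27.70562770562771
mitten_arctic,Arctic mitten,3,hands,0.3,60.6060606060606
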