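hazard_id,food_group,deaths
epec,vegetables,228
etec,vegetables,222
norovirus,vegetables,222
rotavirus,vegetables,222
s_typhi,vegetables,222
shigella,vegetables,222
vibrio,vegetables,222
campylobacter,vegetables,118
nts,vegetables,117
aflatoxin_b1,vegetables,63
arsenic,vegetables,62
epec,dairy,212
etec,dairy,211
norovirus,dairy,211
rotavirus,dairy,211
s_typhi,dairy,211
shigella,dairy,211
vibrio,dairy,211
campylobacter,dairy,125
m_bovis,dairy,123
nts,dairy,123
aflatoxin_b1,dairy,7
arsenic,dairy,6
epec,poultry,129
etec,poultry,128
norovirus,poultry,128
rotavirus,poultry,128
s_typhi,poultry,128
shigella,poultry,128
vibrio,poultry,128
campylobacter,poultry,342
nts,poultry,341
aflatoxin_b1,poultry,2
arsenic,poultry,2
epec,eggs,46
etec,eggs,42
norovirus,eggs,42
rotavirus,eggs,42
s_typhi,eggs,42
shigella,eggs,42
vibrio,eggs,42
campylobacter,eggs,114
nts,eggs,114
aflatoxin_b1,eggs,1
arsenic,eggs,1
epec,beef,162
etec,beef,157
norovirus,beef,157
rotavirus,beef,157
s_typhi,beef,157
shigella,beef,157
vibrio,beef,157
campylobacter,beef,121
nts,beef,120
aflatoxin_b1,beef,6
arsenic,beef,5
epec,small_ruminant_meat,107
etec,small_ruminant_meat,105
norovirus,small_ruminant_meat,105
rotavirus,small_ruminant_meat,105
s_typhi,small_ruminant_meat,105
shigella,small_ruminant_meat,105
vibrio,small_ruminant_meat,105
campylobacter,small_ruminant_meat,80
nts,small_ruminant_meat,80
aflatoxin_b1,small_ruminant_meat,4
arsenic,small_ruminant_meat,4
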