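hazard_id,category,votes
aflatoxin_b1,High,18
aflatoxin_b1,Medium,9
arsenic,High,18
arsenic,Medium,9
m_bovis,High,18
m_bovis,Medium,9
norovirus,High,18
norovirus,Medium,9
s_typhi,High,18
s_typhi,Medium,9
shigella,High,18
shigella,Medium,9
rotavirus,High,18
rotavirus,Medium,9
cryptosporidium,High,3
cryptosporidium,Medium,16
cryptosporidium,Low,8
hepatitis_a,High,3
hepatitis_a,Medium,16
hepatitis_a,Low,8
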