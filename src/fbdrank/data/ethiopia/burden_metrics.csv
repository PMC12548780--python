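hazard_id,metric,best,lower95,upper95
aflatoxin_b1,incidence_rate,0.019,0.00019,0.094
aflatoxin_b1,mortality_rate,0.013,0.00017,0.085
aflatoxin_b1,case_fatality_pct,90.19,90.19,90.19
aflatoxin_b1,daly_rate,0.46,0.0062,3.0
ascaris,incidence_rate,92.0,17.0,164.0
ascaris,mortality_rate,0.0093,1.3e-05,0.01
ascaris,case_fatality_pct,0.011,3.7e-05,0.1
ascaris,daly_rate,6.0,1.0,14.0
brucella,incidence_rate,1.0,0.013,63.0
brucella,mortality_rate,0.65,6.5e-05,2.0
brucella,case_fatality_pct,0.5,0.34,0.66
brucella,daly_rate,0.36,0.004,19.0
campylobacter,incidence_rate,2152.0,309.0,8391.0
campylobacter,mortality_rate,0.75,0.35,1.26
campylobacter,case_fatality_pct,0.034,0.0089,0.23
campylobacter,daly_rate,69.0,32.0,115.0
cryptosporidium,incidence_rate,186.0,0.0,909.0
cryptosporidium,mortality_rate,0.15,0.0,0.53
cryptosporidium,case_fatality_pct,0.075,0.024,0.28
cryptosporidium,daly_rate,12.0,0.0,44.0
dioxins,incidence_rate,0.092,0.003,9.3
dioxins,mortality_rate,0.0,0.0,0.0
dioxins,case_fatality_pct,0.0,0.0,0.0
dioxins,daly_rate,0.11,0.0033,11.0
echinococcus,incidence_rate,2.0,0.5,3.0
echinococcus,mortality_rate,0.017,0.0036,0.054
echinococcus,case_fatality_pct,1.09,0.4,2.51
echinococcus,daly_rate,1.43,0.036,4.0
e_histolytica,incidence_rate,742.0,0.0,4288.0
e_histolytica,mortality_rate,0.05,0.0,0.44
e_histolytica,case_fatality_pct,0.0068,0.001,0.084
e_histolytica,daly_rate,5.0,0.0,40.0
epec,incidence_rate,430.0,17.0,1331.0
epec,mortality_rate,1.67,0.073,3.98
epec,case_fatality_pct,0.38,0.16,0.99
epec,daly_rate,136.0,6.0,321.0
etec,incidence_rate,939.0,141.0,2694.0
etec,mortality_rate,1.27,0.21,2.86
etec,case_fatality_pct,0.13,0.054,0.38
etec,daly_rate,103.0,17.0,236.0
fasciola,incidence_rate,0.0052,0.0018,0.015
fasciola,mortality_rate,0.0,0.0,0.0
fasciola,case_fatality_pct,0.0,0.0,0.0
fasciola,daly_rate,0.038,0.013,0.1
giardia,incidence_rate,663.0,0.0,3060.0
giardia,mortality_rate,0.0,0.0,0.0
giardia,case_fatality_pct,0.0,0.0,0.0
giardia,daly_rate,0.68,0.0,3.0
hepatitis_a,incidence_rate,337.0,45.0,1117.0
hepatitis_a,mortality_rate,0.671,0.097,2.18
hepatitis_a,case_fatality_pct,0.2,0.051,0.79
hepatitis_a,daly_rate,33.0,5.0,103.0
listeria,incidence_rate,0.14,2.5e-05,2.5
listeria,mortality_rate,0.03,5.6e-06,0.055
listeria,case_fatality_pct,22.39,19.24,25.77
listeria,daly_rate,1.0,0.0002,21.0
m_bovis,incidence_rate,7.0,4.0,10.0
m_bovis,mortality_rate,0.37,0.22,0.54
m_bovis,case_fatality_pct,5.48,3.63,8.21
m_bovis,daly_rate,22.0,13.0,32.0
nts,incidence_rate,875.0,100.0,3159.0
nts,mortality_rate,1.55,0.34,2.65
nts,case_fatality_pct,0.17,0.053,0.77
nts,daly_rate,116.0,25.0,201.0
norovirus,incidence_rate,1609.0,0.0,5882.0
norovirus,mortality_rate,1.0,0.0,3.0
norovirus,case_fatality_pct,0.063,0.026,0.14
norovirus,daly_rate,76.0,0.0,226.0
s_paratyphi,incidence_rate,24.0,0.0,87.0
s_paratyphi,mortality_rate,0.157,0.0,0.56
s_paratyphi,case_fatality_pct,0.65,0.65,0.65
s_paratyphi,daly_rate,11.0,0.0,40.0
s_typhi,incidence_rate,106.0,0.0,378.0
s_typhi,mortality_rate,0.68,0.0,2.44
s_typhi,case_fatality_pct,0.65,0.65,0.65
s_typhi,daly_rate,49.0,0.0,174.0
stec,incidence_rate,0.5,0.07,2.0
stec,mortality_rate,5.7e-05,5.2e-06,0.00024
stec,case_fatality_pct,0.011,0.0045,0.024
stec,daly_rate,0.0048,0.0006,0.02
shigella,incidence_rate,435.0,0.0,3296.0
shigella,mortality_rate,0.45,0.0,1.79
shigella,case_fatality_pct,0.093,0.024,0.72
shigella,daly_rate,37.0,0.0,147.0
toxoplasma,incidence_rate,353.0,163.0,617.0
toxoplasma,mortality_rate,0.023,0.0082,0.05
toxoplasma,case_fatality_pct,0.0065,0.0033,0.012
toxoplasma,daly_rate,28.0,13.0,51.0
trichinella,incidence_rate,0.00066,0.00022,0.001
trichinella,mortality_rate,2.4e-05,7.8e-06,4e-05
trichinella,case_fatality_pct,3.57,3.57,3.57
trichinella,daly_rate,0.0014,0.00047,0.0024
vibrio,incidence_rate,72.0,2.0,207.0
vibrio,mortality_rate,2.72,0.075,7.3
vibrio,case_fatality_pct,3.8,2.61,5.01
vibrio,daly_rate,190.0,5.0,511.0
arsenic,incidence_rate,2.39,0.51,4.31
arsenic,mortality_rate,0.65,0.14,1.67
arsenic,case_fatality_pct,27.12,27.12,27.12
arsenic,daly_rate,21.21,4.55,38.2
cadmium,incidence_rate,0.02,0.0003,1.51
cadmium,mortality_rate,0.0056,9e-05,0.37
cadmium,case_fatality_pct,27.0,24.37,28.17
cadmium,daly_rate,0.15,0.002,11.33
lead,incidence_rate,9.46,0.0,85.39
lead,mortality_rate,0.0,0.0,0.0
lead,case_fatality_pct,0.0,0.0,0.0
lead,daly_rate,78.94,0.0,720.85
methylmercury,incidence_rate,3.9,0.75,23.94
methylmercury,mortality_rate,0.0,0.0,0.0
methylmercury,case_fatality_pct,0.0,0.0,0.0
methylmercury,daly_rate,34.68,8.1,196.17
acrylamide,incidence_rate,0.00052,2.5e-05,0.0049
acrylamide,mortality_rate,0.00037,1.7e-05,0.0035
acrylamide,case_fatality_pct,0.54,0.055,0.97
acrylamide,daly_rate,0.012,0.00058,0.12
aflatoxin_m1,incidence_rate,0.001,0.00023,0.0041
aflatoxin_m1,mortality_rate,0.00095,0.0002,0.0036
aflatoxin_m1,case_fatality_pct,0.87,0.84,0.9
aflatoxin_m1,daly_rate,0.036,0.0075,0.14
b_anthracis,incidence_rate,0.06,0.012,0.24
b_anthracis,mortality_rate,0.001,0.00019,0.004
b_anthracis,case_fatality_pct,0.017,0.013,0.02
b_anthracis,daly_rate,0.035,0.0061,0.15
c_botulinum,incidence_rate,0.04,0.02,0.08
c_botulinum,mortality_rate,0.0031,0.00089,0.009
c_botulinum,case_fatality_pct,0.3,0.1,0.5
c_botulinum,daly_rate,0.099,0.018,0.41
lathyrus,incidence_rate,1.7,0.17,17.0
lathyrus,mortality_rate,0.0,0.0,0.0
lathyrus,case_fatality_pct,0.0,0.0,0.0
lathyrus,daly_rate,7.6,0.16,110.0
rvf,incidence_rate,8.8e-06,3.6e-07,9.1e-05
rvf,mortality_rate,7.2e-08,2.4e-09,8.2e-07
rvf,case_fatality_pct,0.01,0.003,0.02
rvf,daly_rate,3.4e-07,4.5e-09,6e-06
rotavirus,incidence_rate,1400.0,450.0,4100.0
rotavirus,mortality_rate,0.74,0.19,2.4
rotavirus,case_fatality_pct,0.00051,0.00047,0.00055
rotavirus,daly_rate,63.0,17.0,200.0
s_aureus,incidence_rate,77.0,51.0,120.0
s_aureus,mortality_rate,0.37,0.16,0.79
s_aureus,case_fatality_pct,0.005,0.0024,0.009
s_aureus,daly_rate,0.12,0.042,0.3
taenia,incidence_rate,850.0,62.0,6300.0
taenia,mortality_rate,0.0,0.0,0.0
taenia,case_fatality_pct,0.0,0.0,0.0
taenia,daly_rate,36.0,0.092,1100.0
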