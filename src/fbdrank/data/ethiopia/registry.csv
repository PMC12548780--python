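id,name,hazard_class,origin,foodborne,is_toxin_producer_only,ecology,fixed_food_group
aflatoxin_b1,Aflatoxin B1,biotoxin,FERG,True,False,chemical,
ascaris,Ascaris spp.,helminth,FERG,True,False,unassigned,
brucella,Brucella spp.,bacterium,FERG,True,False,unassigned,
campylobacter,Campylobacter spp.,bacterium,FERG,True,False,zoonotic,
cryptosporidium,Cryptosporidium spp.,protozoan,FERG,True,False,unassigned,
dioxins,Dioxins,chemical,FERG,True,False,chemical,
echinococcus,Echinococcus granulosus,helminth,FERG,True,False,unassigned,
e_histolytica,Entamoeba histolytica,protozoan,FERG,True,False,unassigned,
epec,Enteropathogenic E. coli (EPEC),bacterium,FERG,True,False,anthroponotic,
etec,Enterotoxigenic E. coli (ETEC),bacterium,FERG,True,False,anthroponotic,
fasciola,Fasciola spp.,helminth,FERG,True,False,unassigned,
giardia,Giardia spp.,protozoan,FERG,True,False,unassigned,
hepatitis_a,Hepatitis A virus,virus,FERG,True,False,unassigned,
listeria,Listeria monocytogenes,bacterium,FERG,True,False,unassigned,
m_bovis,Mycobacterium bovis,bacterium,FERG,True,False,zoonotic,dairy
nts,Nontyphoidal Salmonella enterica,bacterium,FERG,True,False,zoonotic,
norovirus,Norovirus,virus,FERG,True,False,anthroponotic,
s_paratyphi,Salmonella Paratyphi A,bacterium,FERG,True,False,unassigned,
s_typhi,Salmonella Typhi,bacterium,FERG,True,False,anthroponotic,
stec,Shiga toxin-producing E. coli (STEC),bacterium,FERG,True,False,unassigned,
shigella,Shigella spp.,bacterium,FERG,True,False,anthroponotic,
toxoplasma,Toxoplasma gondii,protozoan,FERG,True,False,unassigned,
trichinella,Trichinella spp.,helminth,FERG,True,False,unassigned,
vibrio,Vibrio cholerae,bacterium,FERG,True,False,anthroponotic,
arsenic,Arsenic,chemical,metal,True,False,chemical,
cadmium,Cadmium,chemical,metal,True,False,chemical,
lead,Lead,chemical,metal,True,False,chemical,
methylmercury,Methylmercury,chemical,metal,True,False,chemical,
acrylamide,Acrylamide,chemical,stakeholder,True,False,chemical,
aflatoxin_m1,Aflatoxin M1,biotoxin,stakeholder,True,False,chemical,
b_anthracis,Bacillus anthracis,bacterium,stakeholder,True,False,unassigned,
c_botulinum,Clostridium botulinum,bacterium,stakeholder,True,False,unassigned,
lathyrus,Lathyrus sativus,biotoxin,stakeholder,True,False,chemical,
rvf,Rift Valley Fever virus,virus,stakeholder,True,False,unassigned,
rotavirus,Rotavirus,virus,stakeholder,True,False,anthroponotic,
s_aureus,Staphylococcus aureus,bacterium,stakeholder,True,False,unassigned,
taenia,Taenia saginata,helminth,stakeholder,True,False,unassigned,
coxiella,Coxiella burnetii,bacterium,stakeholder,False,False,unassigned,
a_flavus,Aspergillus flavus,biotoxin,stakeholder,True,True,unassigned,
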