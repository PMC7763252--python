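code,name,subsystem,direction,units
pop_density,Population density,P,negative,person/km2
pop_growth_rate,Natural growth rate of population,P,negative,permille
edu_consolidation_rate,Nine-year compulsory education consolidation rate,P,positive,%
rural_employment_share,Proportion of rural employees,P,positive,%
fertilizer_intensity,Chemical fertilizer application intensity,E,negative,kg/hm2
pesticide_intensity,Pesticide application intensity,E,negative,kg/hm2
disaster_incidence,Natural disaster incidence rate,E,negative,%
human_interference,Human interference index,E,negative,%
sewage_treatment_rate,Domestic sewage treatment rate,E,positive,%
waste_treatment_rate,Domestic waste treatment rate,E,positive,%
gdp_per_capita,Per capita GDP,S,positive,1e4 yuan/person
farmer_net_income,Per capita net income of farmers,S,positive,yuan
tertiary_industry_share,Proportion of tertiary industry in GDP,S,positive,%
economic_density,Economic density,S,positive,1e4 yuan/km2
env_investment_share,Proportion of environmental protection investment to GDP,S,positive,%
land_economic_output,Economic output per unit of land,S,positive,1e4 yuan/km2
woodland_per_capita,Woodland area per capita,N,positive,hm2/person
arable_per_capita,Per capita arable land area,N,positive,hm2/person
grain_per_capita,Per capita output of grain,N,positive,kg/person
forest_cover,Percentage of forest cover,N,positive,%
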