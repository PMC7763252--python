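indicator,subsystem,type_weight,comprehensive_weight
pop_density,P,0.1807,0.0323
pop_growth_rate,P,0.2297,0.0411
edu_consolidation_rate,P,0.3843,0.0687
rural_employment_share,P,0.2053,0.0367
fertilizer_intensity,E,0.2103,0.0580
pesticide_intensity,E,0.1243,0.0343
disaster_incidence,E,0.2030,0.0560
human_interference,E,0.1921,0.0530
sewage_treatment_rate,E,0.0796,0.0220
waste_treatment_rate,E,0.1907,0.0526
gdp_per_capita,S,0.1825,0.0470
farmer_net_income,S,0.1847,0.0476
tertiary_industry_share,S,0.1420,0.0366
economic_density,S,0.2027,0.0522
env_investment_share,S,0.2018,0.0520
land_economic_output,S,0.0863,0.0222
woodland_per_capita,N,0.3112,0.0896
arable_per_capita,N,0.2842,0.0818
grain_per_capita,N,0.2422,0.0697
forest_cover,N,0.1625,0.0468
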