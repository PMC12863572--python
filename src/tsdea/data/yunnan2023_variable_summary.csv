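variable,units,mean,sd,min,max,cv
fiscal_expenditure,CNY per person,10890,6051,3837,47826,0.56
social_sports_instructors,persons per 1000 population,2.74,0.74,1.12,6.39,0.27
sports_venue_area,m2 per person,2.57,0.83,0.78,7.61,0.32
composite_facility_index,service-radius weighted index,1.62,0.81,0.25,4.81,0.50
exercise_participation,percent,39.75,7.61,17.67,63.17,0.19
fitness_pass_rate,percent,92.80,1.90,88.08,98.43,0.02
gdp_per_capita,CNY per person,58041,26844,19064,185336,0.46
urbanization_rate,percent,44.69,17.95,16.42,99.32,0.40
tertiary_industry_share,percent,47.08,10.29,25.88,84.11,0.22
population_density,persons per km2,147.51,202.98,6.94,17911,1.37
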