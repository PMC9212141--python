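code,name,theme,direction,panel_eligible
311,Maternal mortality ratio (per 100 000 live births),Maternal and reproductive health,-1,true
312,Births attended by skilled health personnel (%),Maternal and reproductive health,1,true
371,Demand for family planning satisfied with modern methods (%),Maternal and reproductive health,1,true
372,Adolescent birth rate (per 1000 women aged 15-19 years),Maternal and reproductive health,-1,true
221,Children aged under 5 years stunted (%),Newborn and child health,-1,false
222a,Children aged under 5 years wasted (%),Newborn and child health,-1,false
222b,Children aged under 5 years overweight (%),Newborn and child health,-1,false
222c,Children aged under 5 years underweight (%),Newborn and child health,-1,false
321,Under-five mortality rate (per 1000 live births),Newborn and child health,-1,false
322,Neonatal mortality rate (per 1000 live births),Newborn and child health,-1,true
3b1a,DTP3 immunization coverage among 1-year-olds (%),Newborn and child health,1,false
3b1b,MCV2 immunization coverage (%),Newborn and child health,1,false
3b1c,PCV3 immunization coverage among 1-year-olds (%),Newborn and child health,1,false
331,New HIV infections (per 1000 uninfected population),Infectious diseases,-1,false
332,Incidence of tuberculosis (per 100 000 population per year),Infectious diseases,-1,false
333,Malaria incidence (per 1000 population at risk),Infectious diseases,-1,false
334,Hepatitis B surface antigen prevalence among children under 5 years (%),Infectious diseases,-1,false
335,Reported number of people requiring interventions against NTDs,Infectious diseases,-1,false
341,Probability of dying between age 30 and 70 from NCDs (%),Non-communicable diseases,-1,true
342,Crude suicide rate (per 100 000 population),Non-communicable diseases,-1,true
352,Total alcohol per capita consumption (15+),Non-communicable diseases,-1,false
3a1,Age-standardized prevalence of current tobacco smoking (15+) (%),Non-communicable diseases,-1,false
361,Estimated road traffic death rate (per 100 000 population),Injuries and violence,-1,false
1611,Estimated rate of homicides (per 100 000 population),Injuries and violence,-1,false
391,Air pollution attributable death rate (per 100 000 population),Environmental risks,-1,false
392,Mortality rate attributed to unsafe WASH services (per 100 000 population),Environmental risks,-1,false
393,Mortality rate attributed to unintentional poisoning (per 100 000 population),Environmental risks,-1,true
611,Population using at least basic drinking-water services (%),Environmental risks,1,true
621,Population using at least basic sanitation services (%),Environmental risks,1,true
712,Population with primary reliance on clean fuels and technologies (%),Environmental risks,1,true
1162,Concentrations of fine particulate matter PM2.5,Environmental risks,-1,false
381,UHC service coverage index,Health system coverage,1,false
3c1a,Medical doctors (per 10 000 population),Health system coverage,1,true
3c1b,Nursing and midwifery personnel (per 10 000 population),Health system coverage,1,true
3c1c,Dentists (per 10 000 population),Health system coverage,1,true
3c1d,Pharmacists (per 10 000 population),Health system coverage,1,true
3d1,IHR capacity and health emergency preparedness (SPAR),Health system coverage,1,false
17192,Completeness of cause-of-death data (%),Health system coverage,1,false
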