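country,income_group,gdp_pc_2019,gdp_pc_2030,subregion,excluded_from_subregion_mean
Antigua and Barbuda,Hi,20115.88,22661.78,The Caribbean,false
Bahamas,Hi,36973.56,38530.96,The Caribbean,false
Barbados,Hi,15681.96,16760.34,The Caribbean,false
Saint Kitts and Nevis,Hi,25277.97,29347.63,The Caribbean,false
Trinidad and Tobago,Hi,27231.96,27355.31,The Caribbean,false
Dominica,Up-Mid,12362.03,17114.54,The Caribbean,false
Dominican Republic,Up-Mid,17027.93,28541.57,The Caribbean,false
Grenada,Up-Mid,15952.84,20245.94,The Caribbean,false
Jamaica,Up-Mid,10266.34,11692.23,The Caribbean,false
Saint Lucia,Up-Mid,15018.53,17174.26,The Caribbean,false
Saint Vincent and the Grenadines,Up-Mid,12156.94,16150.12,The Caribbean,false
Haiti,Low,3063.86,2950.10,The Caribbean,false
Belize,Up-Mid,7048.34,6951.27,Central America,false
Costa Rica,Up-Mid,19363.11,25003.16,Central America,false
Panama,Up-Mid,29843.23,41160.17,Central America,false
El Salvador,Low-Mid,8380.18,10354.98,Central America,false
Guatemala,Low-Mid,7885.07,10152.08,Central America,false
Honduras,Low-Mid,5476.92,6790.50,Central America,false
Nicaragua,Low-Mid,5778.65,6762.57,Central America,false
Canada,Hi,48389.86,55097.00,North America,false
United States,Hi,59628.62,75401.22,North America,false
Mexico,Up-Mid,19817.61,22328.21,North America,true
Argentina,Hi,23369.99,23592.87,South America,false
Chile,Hi,23822.12,28380.79,South America,false
Uruguay,Hi,22431.88,26607.68,South America,false
Brazil,Up-Mid,14748.41,17259.89,South America,false
Colombia,Up-Mid,14750.20,18835.73,South America,false
Ecuador,Up-Mid,11649.93,12607.56,South America,false
Guyana,Up-Mid,11815.23,56006.54,South America,true
Paraguay,Up-Mid,12207.68,16123.30,South America,false
Peru,Up-Mid,12457.41,15900.97,South America,false
Suriname,Up-Mid,18326.83,16324.22,South America,false
Bolivia,Low-Mid,8348.02,10416.83,South America,false
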