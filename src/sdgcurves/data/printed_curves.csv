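code,beta_gdp,stars_gdp,beta_gini,stars_gini,beta_health,stars_health,const,stars_const,n_obs,r2,rmse,corr_fe,f_stat
311,-1.0502,3,0.00,0,0.00,0,13.6981,3,230,0.67,0.16,0.36,39.28
312,0.1183,3,0.00,0,0.01,0,3.0204,3,152,0.49,0.20,-0.55,14.62
371,0.5865,3,0.00,0,-0.01,0,-0.90,0,204,0.34,0.14,-0.11,5.72
372,-0.5465,3,0.01,0,-0.0332,1,8.6571,3,116,0.78,0.55,-0.45,65.14
221,-0.6931,3,0.0163,2,-0.01,0,8.4202,3,262,0.46,0.14,,19.36
222a,-0.2507,3,0.00,0,-0.0482,3,4.2305,3,257,0.68,0.54,,78.62
222b,0.2046,3,0.0203,2,0.00,0,-0.9425,1,252,0.35,0.59,,15.72
222c,-0.6239,3,0.0154,1,-0.0471,3,7.4235,3,259,0.73,0.56,,106.82
321,-1.1218,3,0.00,0,-0.0086,2,13.2557,3,492,0.72,0.12,,127.73
322,-0.8628,3,0.0062,1,-0.0124,3,10.1130,3,492,0.68,0.11,-0.28,89.38
3b1a,0.03,0,0.00,0,0.0093,2,3.8931,3,112,0.19,0.18,0.10,2.14
3b1b,0.00,0,-0.01,0,0.01,0,4.4181,3,98,0.32,0.20,0.05,3.36
3b1c,-0.06,0,0.01,0,0.0161,1,4.4335,3,81,0.26,0.26,,1.09
331,-0.10,0,0.0698,2,-0.01,0,-2.02,0,83,0.68,0.98,,23.16
332,-0.8926,3,0.0089,1,0.00,0,11.8466,3,245,0.35,0.08,,20.33
333,-2.1046,1,-0.01,0,-0.1577,1,22.0818,2,114,0.32,0.33,,6.85
334,-0.5736,3,-0.03,0,-0.0604,1,7.1719,3,112,0.57,0.98,,19.54
335,-2.3991,3,0.1477,3,-0.1396,1,28.9117,3,235,0.75,3.03,,131.05
341,-0.2970,3,0.0040,1,-0.0130,3,5.6791,3,490,0.48,0.07,-0.62,72.55
342,-0.2086,2,0.00,0,0.00,0,4.1258,3,490,0.09,0.12,-0.64,4.93
352,0.2479,2,-0.01,0,0.01,0,0.14,0,110,0.61,0.51,-0.23,20.66
3a1,0.01,0,0.00,0,0.00,0,2.2108,2,100,0.51,0.38,,9.47
361,-0.2373,3,0.0192,2,-0.0356,1,4.6921,3,109,0.73,0.39,,63.68
1611,-0.6620,3,-0.01,0,-0.0154,3,8.2065,3,490,0.25,0.21,,27.58
391,-0.3626,3,0.01,0,-0.0316,2,7.2567,3,112,0.56,0.42,,18.31
392,-0.8978,3,0.03,0,-0.01,0,9.4696,3,112,0.86,0.84,-0.17,117.67
393,-0.8568,3,0.0138,2,-0.01,0,7.2751,3,489,0.46,0.17,0.30,33.03
611,0.2190,3,0.00,0,-0.0039,2,2.3409,3,490,0.44,0.04,0.47,18.49
621,0.3421,3,0.00,0,-0.0061,3,1.02,0,491,0.32,0.08,0.06,16.34
712,0.5238,3,0.00,0,0.00,0,-1.08,0,487,0.32,0.12,-0.95,16.74
1162,-0.1882,3,0.00,0,-0.0334,3,4.9046,3,112,0.59,0.36,,20.78
381,0.7602,3,0.00,0,0.00,0,-2.8643,3,487,0.66,0.09,,94.15
3c1a,0.8820,3,0.00,0,-0.02,0,-6.0251,3,291,0.19,0.16,0.55,11.78
3c1b,0.4934,2,0.00,0,0.00,0,-1.44,0,294,0.05,0.20,0.09,3.04
3c1c,1.3176,3,-0.01,0,-0.02,0,-11.3952,2,250,0.13,0.32,-0.11,5.95
3c1d,1.5310,3,0.01,0,-0.02,0,-13.9894,2,226,0.18,0.29,-0.88,5.08
3d1,0.5413,3,-0.01,0,0.00,0,-0.65,0,240,0.14,0.09,,7.72
17192,0.14,0,-0.01,0,0.02,0,3.2379,3,77,0.41,0.33,,2.04
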