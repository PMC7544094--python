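rsid,chromosome,position,short_allele,long_allele,short_allele_freq,gene_is_telomere_maintenance,n_participants,gwas,population
rs621559,1,43179740,G,A,0.908,no,1619,true,"Texas, no ethnicity criteria"
rs3219104,1,226374920,A,C,0.183,yes,23096,true,Singapore Chinese
rs1805087,1,236885200,A,G,0.804,no,989,false,Non-Hispanic White Female
rs11125529,2,54248729,C,A,0.875,no,37684,true,European
rs11890390,2,54258545,C,T,0.858,no,60061,true,Singapore Chinese European
rs6772228,3,58390292,A,T,0.056,no,26089,true,European
rs55749605,3,101513249,A,C,0.637,yes,78592,true,European
rs12638862,3,169759718,G,A,0.272,yes,5075,true,Bangladeshi
rs12696304,3,169763483,G,C,0.281,yes,9492,true,European
rs2293607,3,169764547,C,T,0.249,yes,2953,false,"American, European"
rs10936599,3,169774313,T,C,0.245,yes,37684,true,European
rs1317082,3,169779797,G,A,0.249,yes,9190,true,European
rs3772190,3,169782699,A,G,0.147,yes,3417,false,European African-American
rs10936600,3,169796797,T,A,0.229,yes,78592,true,European
rs16847897,3,169850328,C,G,0.282,yes,9492,true,European
rs1920116,3,169862183,A,G,0.285,yes,37684,true,European
rs13137667,4,70908630,T,C,0.032,no,78592,true,European
rs7680468,4,107383042,T,G,0.031,no,4289,true,Caucasian (American + Danish) w/ Familial Longevity
rs7675998,4,163086668,A,G,0.227,yes,37684,true,European
rs4691895,4,163127047,G,C,0.236,yes,78592,true,European
rs10857352,4,163180330,A,G,0.581,yes,23096,true,Singapore Chinese
rs2075786,5,1266195,G,A,0.640,yes,207,false,Chinese w/ Schizophrenia + Healthy
rs10054203,5,1279849,G,C,0.571,yes,774,false,Chinese
rs7726159,5,1282204,C,A,0.694,yes,26089,true,European
rs7705526,5,1285859,C,A,0.660,yes,5075,true,Bangladeshi
rs2736100,5,1286401,A,C,0.496,yes,6549,true,Han Chinese (Healthy + T2DM)
rs2853677,5,1287079,A,G,0.586,yes,78592,true,European
rs2736108,5,1297373,C,T,0.733,yes,15567,false,European
rs401681,5,1321972,T,C,0.433,yes,1208,false,Caucasian
rs2966952,5,7867917,T,C,0.169,no,989,false,Non-Hispanic White Female
rs3733890,5,79126136,A,G,0.304,no,989,false,Non-Hispanic White Female
rs34991172,6,25480100,G,T,0.073,no,78592,true,European
rs1800629,6,31575254,G,A,0.845,no,840,false,European (Spain) w/ CHD
rs2736176,6,31619784,G,C,0.696,no,78592,true,European
rs558702,6,31902549,A,G,0.097,no,989,false,Non-Hispanic White Female
rs654128,6,116765215,C,A,0.846,no,1619,true,"Texas, no ethnicity criteria"
rs59294613,7,124914213,A,C,0.291,yes,78592,true,European
rs7776744,7,124959695,G,A,0.590,yes,23096,true,Singapore Chinese
rs11991621,8,9549072,T,C,0.164,yes,3646,false,Non-Hispanic White (M) Caucasian (F)
rs6990097,8,9555347,T,C,0.740,yes,,false,Swedish Female
rs12549064,8,9584517,C,A,0.171,yes,3646,false,Non-Hispanic White (M) Caucasian (F)
rs10903314,8,9609596,T,C,0.258,yes,3646,false,Non-Hispanic White (M) Caucasian (F)
rs6990300,8,9690351,G,A,0.334,yes,3646,false,Non-Hispanic White (M) Caucasian (F)
rs11249943,8,9750353,C,A,0.185,yes,3646,false,Non-Hispanic White (M) Caucasian (F)
rs17150478,8,9783524,G,A,0.167,yes,3646,false,Non-Hispanic White (M) Caucasian (F)
rs28365964,8,73008648,T,C,0.999,yes,23096,true,Singapore Chinese
rs10466239,10,43354379,C,T,0.918,unknown,4289,false,Caucasian (American + Danish) w/ Familial Longevity
rs7095953,10,99514668,C,T,0.267,no,60061,true,Singapore Chinese European
rs7100920,10,103881220,T,C,0.491,yes,4289,false,Caucasian (American + Danish) w/ Familial Longevity
rs2067832,10,103883376,A,G,0.487,yes,4289,false,Caucasian (American + Danish) w/ Familial Longevity
rs10786775,10,103897558,C,G,0.897,yes,2353,false,"European (Healthy, CHD, T2DM)"
rs2487999,10,103900068,C,T,0.896,yes,26089,true,European
rs9419958,10,103916188,C,T,0.852,yes,9190,true,European
rs9420907,10,103916707,A,C,0.828,yes,37684,true,European
rs4387287,10,103918139,C,A,0.819,yes,3417,true,European African-American
rs12415148,10,103920828,T,C,0.999,yes,23096,true,Singapore Chinese
rs669976,11,64806117,C,T,0.102,yes,3646,false,Non-Hispanic White (M) Caucasian (F)
rs524386,11,64817487,C,T,0.103,yes,3646,false,Non-Hispanic White (M) Caucasian (F)
rs2957154,11,64817515,C,T,0.264,yes,3646,false,Non-Hispanic White (M) Caucasian (F)
rs670358,11,64824207,A,G,0.118,yes,3646,false,Non-Hispanic White (M) Caucasian (F)
rs660339,11,73978059,G,A,0.598,no,950,false,Australian Caucasian
rs659366,11,73983709,C,T,0.627,no,950,false,Australian Caucasian
rs12270338,11,94414298,C,A,0.791,yes,3646,false,Non-Hispanic White (M) Caucasian (F)
rs13447720,11,94432160,T,C,0.784,yes,3646,false,Non-Hispanic White (M) Caucasian (F)
rs1801516,11,70025996,G,A,0.865,yes,989,false,Non-Hispanic White Female
rs228595,11,108234866,A,G,0.427,yes,78592,true,European
rs227080,11,108377161,G,A,0.529,yes,23096,true,Singapore Chinese
rs12299470,12,3528284,G,A,0.873,no,989,false,Non-Hispanic White Female
rs2630578,12,32152853,C,G,0.178,no,843,false,>98.5% European w/ CAD
rs1151026,12,32176235,G,A,0.200,no,843,false,>98.5% European w/ CAD
rs17653722,12,52193734,G,T,0.833,no,6549,true,Han Chinese (Healthy + T2DM)
rs938886,14,20369542,G,C,0.761,yes,100,false,Swedish Female
rs4246977,14,20414432,C,T,0.389,yes,100,false,Swedish Female
rs41293836,14,24252121,C,T,0.998,yes,23096,true,Singapore Chinese
rs1483898,14,42336702,T,A,0.857,no,492,true,African American Children/Adolescents
rs398652,14,56058851,G,A,0.840,unknown,1619,true,"Texas, no ethnicity criteria"
rs2302588,14,72938044,G,C,0.897,no,60061,true,Singapore Chinese European
rs2535913,14,72948525,A,G,0.255,no,20022,true,European
rs10046,15,51210789,G,A,0.503,no,2143,false,Anglo-Celtic Australian Males
rs2899470,15,51211480,T,G,0.407,no,2143,false,Anglo-Celtic Australian Males
rs700518,15,51236915,T,C,0.527,no,2143,false,Anglo-Celtic Australian Males
rs17817449,16,53779455,G,T,0.398,no,783,false,Prague Women
rs9939609,16,53786615,A,T,0.412,no,1184,false,Korean
rs74019828,16,58175370,A,G,0.076,no,4013,true,Punjabi Sikh w/ T2DM
rs3785074,16,69373083,A,G,0.705,yes,78592,true,European
rs62053580,16,74646176,G,A,0.147,no,78592,true,European
rs7194734,16,82166375,T,C,0.783,no,78592,true,European
rs2967374,16,82176256,G,A,0.788,no,60061,true,Singapore Chinese European
rs3027234,17,8232774,T,C,0.163,yes,11416,true,European
rs78148049,17,64655172,NA,NA,NA,no,4289,false,Caucasian (American + Danish) w/ Familial Longevity
rs820152,17,75620008,C,T,0.372,yes,3646,false,Non-Hispanic White (M) Caucasian (F)
rs1001761,18,662103,A,G,0.473,no,60061,true,Singapore Chinese European
rs2162440,18,37634043,G,A,0.795,unknown,2790,true,European (F)
rs7235755,18,37636298,G,A,0.784,no,2790,true,European (F)
rs8105767,19,22032639,A,G,0.686,no,37684,true,European
rs7253490,19,22110904,C,A,0.685,no,60061,true,Singapore Chinese European
rs412658,19,22176638,C,T,0.646,no,11416,true,European
rs6028466,20,39500359,G,A,0.939,unknown,1619,true,"Texas, no ethnicity criteria"
rs73598374,20,44651586,T,C,0.065,yes,168,false,Italian-Caucasian
rs75691080,20,63638397,T,C,0.100,yes,78592,true,European
rs34978822,20,63660246,G,C,0.018,yes,78592,true,European
rs41309367,20,63678201,T,C,0.701,yes,23096,true,Singapore Chinese
rs6010620,20,63678486,G,A,0.774,yes,37684,true,European
rs2297439,20,63679775,G,T,0.083,yes,5075,true,Bangladeshi
rs755017,20,63790269,A,G,0.874,yes,37684,true,European
rs73624724,20,63805045,T,C,0.864,yes,78592,true,European
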