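cee_id,subspecies,group_size,cee_type,rl_max_db,rl_low_db,rl_high_db,med_whist,iqr_whist,cpt_mean_pre,cpt_mean_exposure,cpt_var_pre,cpt_var_exposure
2019_01,Db,260,mfas,147,140,147,6.96,6.39,26,39,5,1
2019_02,Dd,350,control,,,,4.80,5.19,37,29,0,5
2019_04,Db,200,control,,,,0.25,0.77,2,0,4,2
2019_06,Db,45,control,,,,0.32,1.38,5,0,4,9
2019_07,Db,300,mfas,154,150,154,3.11,3.81,36,20,3,3
2019_08,Db,250,mfas,142,131,142,1.50,3.91,30,12,4,4
2019_09,Dd,250,control,,,,4.21,5.38,46,44,2,4
2019_10,Dd,30,mfas,149,146,149,0.091,0.38,0,0,3,7
2021_01,Db,150,control,,,,3.14,4.47,3,51,1,3
2021_02,Db,200,control,,,,4.68,3.89,18,29,0,4
2021_03,Dd,150,control,,,,0.99,2.01,11,0,2,0
2021_04,Db,150,control,,,,4.66,4.20,27,37,4,2
2021_05,Dd,250,control,,,,0.36,1.87,0,5,8,4
2021_08,Db,30,mfas,153,145,153,14.13,7.85,50,49,2,4
2021_09,Db,200,mfas,157,152,157,1.17,2.17,3,6,2,2
2021_10,Db,300,mfas,159,150,159,15.34,9.16,42,61,3,2
2021_11,Db,10,mfas,153,150,153,0.0029,0.063,0,0,0,6
2021_12,Dd,150,mfas,152,149,152,2.85,3.07,7,24,4,6
2021_13,Dd,200,mfas,147,139,147,2.21,4.73,2,2,9,4
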