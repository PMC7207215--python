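crop_name,ktmp,t_abs_min,t_opt_min,t_opt_max,t_abs_max,r_abs_min,r_opt_min,r_opt_max,r_abs_max,season_length,plant_any_month
cassava,0,10,20,29,35,500,1000,1500,5000,9,False
cowpea,0,8,20,35,41,300,500,1100,1500,3,False
groundnut,0,10,22,28,45,300,500,1000,1300,4,False
maize,0,10,18,33,47,400,600,1200,1800,4,False
pearl_millet,0,12,25,35,40,200,400,900,1700,3,False
plantain,8,10,20,30,40,700,1200,2500,5000,12,True
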