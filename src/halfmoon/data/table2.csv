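site,zone,exp_id,exp_year,exp_area_ha,ctrl_id,ctrl_year,ctrl_area_ha,ndvi_baseline_control,ndvi_baseline_experiment,ndvi_experiment_control,ndvi_experiment_experiment
Dan Goudau,pastoral,1,2013,370,0,2018,110,0.118,0.121,0.122,0.154
Dan Gueza,agricultural,0,2015,310,6,2018,50,0.130,0.148,0.149,0.180
Dargue,pastoral,4,2016,90,3,2019,11,0.124,0.127,0.149,0.176
Djero,pastoral,2,2013,17,1,2017,14,0.101,0.118,0.088,0.157
Gougouhema,pastoral,1,2014,67,11,2019,30,0.100,0.094,0.113,0.121
Karkara,pastoral,0,2014,59,9,2018,15,0.122,0.110,0.143,0.177
Satara,pastoral,2,2013,13,4,2019,47,0.065,0.060,0.087,0.105
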