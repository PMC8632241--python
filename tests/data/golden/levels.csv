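peptide_id,nominal_conc,n_replicates,mean_ratio,cv_percent,usable
PEP001,0,0,,,False
PEP001,0.205,1,0.008532787459,,False
PEP001,0.512,3,0.009722702928,32.326502,True
PEP001,1.28,3,0.01144958737,15.9781176,True
PEP001,3.2,4,0.02334584069,10.18541943,True
PEP001,8,4,0.04535240999,3.028603415,True
PEP001,20,4,0.1073519366,4.951387361,True
PEP001,200,4,0.9878606264,5.30719805,True
PEP001,2000,4,9.693063291,3.267939813,True
PEP002,0,0,,,False
PEP002,0.205,4,0.009505438382,31.82479341,True
PEP002,0.512,4,0.007641306973,19.17443786,True
PEP002,1.28,4,0.01375533578,25.23922161,True
PEP002,3.2,4,0.02450999888,17.59085497,True
PEP002,8,4,0.04777294723,6.492231439,True
PEP002,20,4,0.1063606409,3.995463497,True
PEP002,200,4,1.001941847,5.549118052,True
PEP002,2000,4,9.918727591,5.13227741,True
PEP003,0,0,,,False
PEP003,0.205,1,0.00925070595,,False
PEP003,0.512,4,0.008865056168,23.30441745,True
PEP003,1.28,4,0.01272832663,26.97578977,True
PEP003,3.2,4,0.0216203062,10.37919889,True
PEP003,8,4,0.048494708,9.066984156,True
PEP003,20,4,0.104832959,4.459042646,True
PEP003,200,4,0.9568468897,10.95072279,True
PEP003,2000,4,9.958423674,3.288654286,True
PEP004,0,0,,,False
PEP004,0.205,3,0.007402167745,2.911515645,True
PEP004,0.512,2,0.01183568693,31.89187562,False
PEP004,1.28,4,0.01252161629,7.833455905,True
PEP004,3.2,4,0.02149194566,10.40148303,True
PEP004,8,4,0.04696681637,2.437828055,True
PEP004,20,4,0.1106154329,1.150501145,True
PEP004,200,4,0.9761952541,2.442883968,True
PEP004,2000,4,9.757518828,3.929158334,True
PEP005,0,0,,,False
PEP005,0.205,3,0.01362676064,30.21772699,True
PEP005,0.512,4,0.009013876235,31.82087898,True
PEP005,1.28,4,0.01419579245,29.70902355,True
PEP005,3.2,4,0.02656179528,14.48486823,True
PEP005,8,4,0.0480699339,6.454425655,True
PEP005,20,4,0.1040896634,5.274584926,True
PEP005,200,4,1.023555158,3.520204328,True
PEP005,2000,4,9.702206813,3.371472949,True
PEP006,0,0,,,False
PEP006,0.205,3,0.01012368604,43.84907009,True
PEP006,0.512,3,0.00903659936,12.34820223,True
PEP006,1.28,4,0.01487535152,20.17706386,True
PEP006,3.2,4,0.02304577966,14.12600888,True
PEP006,8,4,0.05152981835,1.903117777,True
PEP006,20,4,0.1067166313,2.154791873,True
PEP006,200,4,0.9612158585,3.191589,True
PEP006,2000,4,9.751241203,2.813931597,True
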