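peptide_id,condition,cv_percent,pct_diff,stable_flag
PEP001,4C_48h,0.4284705086,0.8162439784,True
PEP001,4C_8h,1.124763822,0.2322288464,True
PEP001,freeze_thaw_x2,1.037996183,0.5947883571,True
PEP001,minus80_5wk,0.5150996603,0.4967213899,True
PEP002,4C_48h,0.6045736254,1.046164049,True
PEP002,4C_8h,1.242280227,0.07393396875,True
PEP002,freeze_thaw_x2,1.015190372,0.1391508172,True
PEP002,minus80_5wk,0.7731266505,1.126311661,True
PEP003,4C_48h,2.234694596,0.1786777182,True
PEP003,4C_8h,1.430672513,0.9436850753,True
PEP003,freeze_thaw_x2,0.7799751073,0.889876757,True
PEP003,minus80_5wk,0.6179449007,0.6224676567,True
PEP004,4C_48h,0.7874868395,0.1959876414,True
PEP004,4C_8h,0.1895173808,0.8649308968,True
PEP004,freeze_thaw_x2,0.1241003342,0.122811186,True
PEP004,minus80_5wk,0.5317977362,0.7123028402,True
PEP005,4C_48h,0.7380707782,0.2462239095,True
PEP005,4C_8h,0.8001283015,1.431620425,True
PEP005,freeze_thaw_x2,1.035927693,0.5026457495,True
PEP005,minus80_5wk,0.7589168636,0.2779113747,True
PEP006,4C_48h,0.403568121,0.02671870964,True
PEP006,4C_8h,0.3581944399,1.189325132,True
PEP006,freeze_thaw_x2,0.5773914152,0.1484597389,True
PEP006,minus80_5wk,1.142481542,0.8250570789,True
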