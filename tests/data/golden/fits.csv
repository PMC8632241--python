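peptide_id,lloq,uloq,slope,intercept,r2,dynamic_range_orders,status,uloq_is_minimum,n_levels_used
PEP001,1.28,2000,0.9251423436,-2.11546357,0.9974156169,3.193820026,ok,True,6
PEP002,3.2,2000,0.9439969201,-2.150653025,0.9981562863,2.795880017,ok,True,5
PEP003,3.2,2000,0.953810348,-2.181469086,0.9989823971,2.795880017,ok,True,5
PEP004,0.205,2000,0.8213442645,-1.907922068,0.9697771323,3.989276135,ok,True,7
PEP005,3.2,2000,0.9344927984,-2.12927153,0.9969805409,2.795880017,ok,True,5
PEP006,3.2,2000,0.9404633368,-2.14834763,0.9987299498,2.795880017,ok,True,5
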