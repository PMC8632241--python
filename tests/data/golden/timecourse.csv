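peptide_id,timepoint_h,normalized_ratio,plateau_time_h
PEP001,2,0.5437780668,24
PEP001,6,0.845078,24
PEP001,16,0.9340281916,24
PEP001,24,1,24
PEP002,2,0.5346658905,16
PEP002,6,0.8209920454,16
PEP002,16,1,16
PEP002,24,0.9669662305,16
PEP003,2,0.5573597344,16
PEP003,6,0.8215457171,16
PEP003,16,1,16
PEP003,24,0.9731658466,16
PEP004,2,0.548240494,16
PEP004,6,0.8063709534,16
PEP004,16,0.9881773623,16
PEP004,24,1,16
PEP005,2,0.5411292553,16
PEP005,6,0.882936569,16
PEP005,16,0.9876239648,16
PEP005,24,1,16
PEP006,2,0.5558018615,16
PEP006,6,0.7999582636,16
PEP006,16,0.9866661198,16
PEP006,24,1,16
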