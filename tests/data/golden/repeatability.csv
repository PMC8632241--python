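peptide_id,spike_level,intra_cv,inter_cv,n_days,n_reps_per_day
PEP001,high,2.571764101,13.09124104,5,3
PEP001,low,3.649500771,12.63336596,5,3
PEP001,medium,4.460936138,11.99156754,5,3
PEP002,high,3.505703808,5.330670611,5,3
PEP002,low,3.677595798,6.893586631,5,3
PEP002,medium,2.470599051,4.697028217,5,3
PEP003,high,4.57232206,5.495348472,5,3
PEP003,low,3.900624172,5.674801567,5,3
PEP003,medium,2.690721451,2.768253678,5,3
PEP004,high,5.878072708,7.75543505,5,3
PEP004,low,6.124306006,9.789570206,5,3
PEP004,medium,3.491588542,6.661996192,5,3
PEP005,high,5.354416407,6.102244784,5,3
PEP005,low,5.31113198,6.144228951,5,3
PEP005,medium,4.447807213,7.188649297,5,3
PEP006,high,3.905256995,4.092044653,5,3
PEP006,low,6.921517742,6.284384257,5,3
PEP006,medium,3.913247004,4.271970876,5,3
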