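peptide_id,tumor_001,tumor_002,tumor_003,tumor_004,tumor_005,tumor_006,tumor_007,tumor_008,tumor_009,tumor_010,tumor_011,tumor_012,tumor_013,tumor_014,tumor_015,tumor_016,tumor_017,tumor_018,tumor_019,tumor_020,tumor_021,tumor_022,tumor_023,tumor_024,tumor_025,tumor_026,tumor_027,tumor_028,tumor_029,tumor_030,tumor_031,tumor_032,tumor_033,tumor_034,tumor_035,tumor_036,tumor_037,tumor_038,tumor_039,tumor_040
PEP001,-0.8808974625,-0.239940064,1.213204666,-1.356571566,-0.2021015303,1.083376653,0.9500219253,0.2289915976,-0.742113519,-1.405993929,0.2193713211,0.2132734865,0.9913073583,-0.9626172404,-1.155840977,0.1503359571,0.6192739362,-0.981327926,-0.1723421137,1.57582635,-1.053013891,0.3183386755,-0.6369503783,-0.3742227521,-1.26619024,0.2969474128,0.7899817841,0.8156222285,-0.02470132854,0.4756026687,1.849597609,2.580969302,-0.7603237014,-1.334425274,-0.6548674784,-1.044373533,-0.6653419482,0.8702540044,1.473105293,-0.8012453758
PEP002,0.1773742582,0.8423329893,0.6292532265,-0.8816504864,0.1400995535,1.384901024,-0.571375917,1.09422526,-0.3961430541,-0.3821520595,0.07874970103,-0.9082458115,1.270894069,-1.196610434,-0.5469789732,-0.9459325908,-0.5747520283,-0.82160806,-0.6135671005,-0.1367578526,-0.3596168084,0.09874196652,0.2543937069,-1.378245252,-1.190395168,1.716216251,1.812544903,0.3974612231,-0.4170627813,0.4829595462,-1.229625447,0.7127312814,-1.364613152,1.737197609,1.867822724,-1.019466768,-0.07093016929,-0.2976035212,-1.250908433,1.856342576
PEP003,-0.1562247499,-0.8644423236,1.524512683,-1.281792628,0.5963932299,-1.371887862,0.8635600781,-0.793758988,0.5341459247,1.111097527,-0.1471289779,-0.5375939233,1.529399177,0.1052704254,-0.1019041866,1.037407658,0.8223326731,1.395337418,0.217060788,-1.037726012,-1.152494562,0.09357259731,3.014806662,1.230730551,-0.3796917196,-1.063045242,0.9584685647,0.542317056,-1.106657269,-0.5865744612,-1.272344215,-1.167314547,-0.674680007,-0.3268200238,-0.1676404013,0.05496399659,-0.8043850457,0.4584104241,0.002002884848,-1.097683176
PEP004,-0.9845037627,-1.019402127,-0.4933425186,0.8379936216,-0.7177686205,-0.5467535929,-0.8638545459,-1.08660314,-1.051505952,0.4946953002,-0.2603797861,-1.111997858,-0.7910187493,-1.012067055,1.015059775,1.885199154,-0.2053100607,1.16513443,-1.130527521,-0.7161029673,0.7583200668,-0.4687140795,-0.5548285177,0.4344727884,-0.6148152209,0.6255731861,2.123809824,0.6875017646,-0.7304012227,0.81619942,0.6412586229,0.2399811311,-1.395349059,-0.739895901,0.902766563,0.9163000234,2.327478738,0.08809371439,-0.9146408316,1.449944966
PEP005,-1.579821417,-0.4850334196,-1.474732351,0.3286938239,0.9622030941,-0.09396637765,-1.007856,-1.191340433,1.813744592,-0.8256663911,,-0.845168255,-0.5532269665,1.126103337,0.1210124047,0.9794726593,1.190960375,-0.5713067128,0.6609381292,-0.9717521682,,0.09367267407,-1.200253706,-0.1031370246,,1.740465967,0.1041076539,1.029767061,1.538054047,0.4429010253,0.3866718206,-1.364263755,-1.318711359,1.430723154,-0.6704872385,-0.483766699,-0.2784695008,0.5123347385,-0.7603541564,1.317487376
PEP006,-0.1549403858,-0.8709531422,,0.4342356674,-0.005938570412,,-1.766474637,1.173201681,-0.04549494213,0.8591746048,0.6334580986,-1.562000833,,,,2.038659624,0.7541695306,-1.014865447,-1.007309956,,1.964839136,0.8102040349,0.03411131499,,0.553003075,-1.16358916,-1.553547355,0.6654613709,-0.2694064858,-0.5308290272,1.212638081,0.6360840113,-0.3276329962,-0.7749806928,0.3325709039,-0.008447370677,-0.9570426912,0.9995929921,-1.087950434,
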