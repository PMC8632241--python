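sample_id,n_detected
tumor_001,6
tumor_002,6
tumor_003,5
tumor_004,6
tumor_005,6
tumor_006,5
tumor_007,6
tumor_008,6
tumor_009,6
tumor_010,6
tumor_011,5
tumor_012,6
tumor_013,5
tumor_014,5
tumor_015,5
tumor_016,6
tumor_017,6
tumor_018,6
tumor_019,6
tumor_020,5
tumor_021,5
tumor_022,6
tumor_023,6
tumor_024,5
tumor_025,5
tumor_026,6
tumor_027,6
tumor_028,6
tumor_029,6
tumor_030,6
tumor_031,6
tumor_032,6
tumor_033,6
tumor_034,6
tumor_035,6
tumor_036,6
tumor_037,6
tumor_038,6
tumor_039,6
tumor_040,5
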