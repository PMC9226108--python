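study_id,sex,age,height_m,bmi
PKD_003,M,46,1.89,27.80
PKD_004,M,50,1.81,32.17
PKD_005,F,60,1.66,28.12
PKD_006,M,55,1.91,23.27
PKD_008,F,32,1.63,22.96
PKD_009,M,75,1.72,32.89
PKD_010,F,69,1.63,20.81
PKD_011,F,56,1.65,30.89
PKD_012,F,45,1.63,27.93
PKD_013,M,37,1.75,27.84
PKD_014,F,60,1.60,32.90
PKD_015,F,40,1.69,27.99
PKD_016,F,42,1.65,25.49
PKD_017,M,43,1.88,28.52
PKD_018,F,35,1.71,27.15
PKD_019,M,40,1.78,28.25
PKD_020,F,70,1.75,24.37
PKD_021,M,70,1.86,32.89
PKD_024,F,70,1.56,27.20
PKD_026,F,38,1.62,31.36
PKD_027,F,28,1.66,23.22
PKD_028,F,62,1.65,29.90
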