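patient_id,age,sex,vol_right_ml,vol_left_ml,attenuation_lo_hu,attenuation_hi_hu,midline_shift_mm
P1,63,M,104,,26,26,7
P2,90,F,116,18,22,49,7
P3,81,M,,174,26,49,4
P4,67,M,163,,32,58,14
P5,87,M,,67,24,54,1
P6,75,F,15,50,17,43,4
P7,86,M,143,,30,30,6
P8,67,M,20,87,35,55,6
P9,81,M,75,,23,59,4
P10,76,F,108,102,31,41,2
P11,65,M,,104,25,29,8
P12,67,M,94,,37,51,7
P13,88,F,,43,28,41,6
P14,63,M,,114,50,61,8
P15,54,F,27,,30,39,4
P16,76,F,39,22,22,54,0
P17,67,F,112,,18,18,12
P18,86,M,,144,32,57,5
P19,88,F,,118,23,53,7
P20,85,M,105,67,24,50,3
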