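participant_id,side,age,sex,ms_type,chronicity,intervention_group,edss,arat_pre,arat_post,bbt_pre,bbt_post,nhpt_pre,nhpt_post
01,left,52,F,RR,29,1,7.0,37,49,22,33,45.25,41.14
01,right,52,F,RR,29,1,7.0,47,56,31,47,24.75,23.43
02,right,69,M,PP,19,1,7.5,44,41,20,26,140.27,216.4
03,left,25,F,RR,6,2,6.0,52,57,45,57,29.35,23.78
03,right,25,F,RR,6,2,6.0,53,55,43,52,29.62,23.81
04,left,42,F,RR,1,1,4.0,56,56,39,57,27.81,23.52
04,right,42,F,RR,1,1,4.0,54,55,40,65,20.48,20.92
05,left,56,F,SP,10,2,7.0,49,54,38,44,33.72,35.3
05,right,56,F,SP,10,2,7.0,29,40,25,28,89.79,70.24
06,left,65,M,SP,19,2,8.0,52,54,34,34,39.9,44.13
07,left,63,F,RR,8,2,4.5,57,57,60,49,20.84,22.28
07,right,63,F,RR,8,2,4.5,54,55,47,45,35.04,27.3
08,left,76,F,RR,38,1,5.0,43,54,42,56,27.01,24.61
08,right,76,F,RR,38,1,5.0,34,54,43,49,34.46,23.46
09,left,60,M,PP,21,1,7.0,52,54,44,49,31.48,35.66
09,right,60,M,PP,21,1,7.0,53,55,51,48,25.29,41.93
10,left,46,M,PP,11,2,5.5,55,56,32,43,30.58,39.08
10,right,46,M,PP,11,2,5.5,56,56,35,53,23.23,20.83
11,left,70,F,RR,37,3,6.0,53,55,45,39,29.86,35.28
11,right,70,F,RR,37,3,6.0,45,52,42,41,53.21,46.19
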