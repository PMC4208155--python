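subject_id,side,knee_system,age,sex,bmi
1,right,UKA,52,M,29.4
2,right,TKA,57,F,24.2
3,right,TKA,63,M,22.7
4,left,TKA,68,M,27.1
5,left,TKA,57,F,28.9
6,left,UKA,64,F,24.5
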