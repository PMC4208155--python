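subject_id,timepoint,walking_speed,cadence,step_length,running_speed,stairs_time_per_step_up,stairs_time_per_step_down,stairs_max_flexion_up,stairs_max_flexion_down,stairs_flexion_at_heelstrike_down,power_acceleration,power_deceleration
1,pre,0.92,104,0.5,1.06,0.6,0.54,78,81,25,2,4.2
1,post,1.25,122,0.6,1.36,0.58,0.51,84,84,27,1.4,3.1
2,pre,1.44,117,0.7,2.08,0.5,0.51,74,72,22,5.7,2.1
2,post,1.67,126,0.8,2.69,0.43,0.41,77,69,26,2.6,3.4
3,pre,1.5,114,0.8,2.42,0.51,0.49,83,70,6,7.4,1.7
3,post,1.5,116,0.8,3.03,0.5,0.4,78,69,20,4.2,2.9
4,pre,1,100,0.6,1.58,0.75,0.59,49,36,8,3.4,1.9
4,post,1.44,124,0.7,1.75,0.64,0.58,87,74,12,3.1,2.3
5,pre,1.22,116,0.6,1.25,0.57,0.53,93,101,18,2.2,1.8
5,post,1.39,120,0.7,2.11,0.5,0.44,75,78,24,3.3,3.4
6,pre,1.25,111,0.7,1.58,0.66,0.65,86,84,7,1.8,1.9
6,post,1.39,116,0.7,1.86,0.67,0.53,72,84,25,2.8,2.5
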