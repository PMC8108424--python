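id,target,trajectory,recording_channels,stimulation_channel,current_ma,pre,macro_stim,percent_change,paired_pulse,directional
P01,STN,1,2-3,0-1,1.6,34.5,14.5,58.0,Yes,No
P02,STN,1,0-1,2-3,1.5,NA,NA,NA,Yes,No
P02,STN,2,0-3,1-2,2.1,23.0,10.0,56.5,Yes,No
P03,STN,1,2-3,0-1,2.1,22.0,10.0,54.5,Yes,No
P04,STN,1,2-3,0-1,1.9,15.0,7.5,50.0,Yes,No
P05,STN,1,2-3,0-1,1.3,30.0,12.0,60.0,Yes,No
P06,STN,1,0-3,1-2,1.2,18.0,12.0,33.3,Yes,No
P07,STN,1,"2A,2B,2C,3A,3B,3C",1-4,2.5,8.0,2.0,75.0,Yes,Yes
P08,GPi,1,0-2,1-3,NA,26.5,11.5,56.6,No,No
P09,GPi,1,1-2,0-3,2.5,26.0,4.0,84.6,No,No
P10,GPi,1,1-2,0-3,2.7,20.0,9.5,52.5,No,No
P11,GPi,1,1-2,0-3,1.9,29.0,5.5,81.0,No,No
P12,GPi,1,"2A,2B,2C,3A,3B,3C",1-4,3.0,21.0,6.0,71.4,Yes,Yes
P13,VIM,1,2-3,0-1,2.2,9.5,3.0,68.4,Yes,No
P14,VIM,1,2-3,0-1,2.7,6.0,4.0,33.3,Yes,No
P14,VIM,2,2-3,0-1,3.0,6.0,3.0,50.0,Yes,No
P15,VIM,1,2-3,0-1,1.5,12.0,2.0,83.3,Yes,No
P16,VIM,1,2-3,0-1,2.1,11.0,0.5,95.5,Yes,No
P17,VIM,1,2-3,0-1,2.0,7.5,4.0,46.7,Yes,No
P18,VIM,1,2-3,0-1,2.6,21.0,17.5,16.7,Yes,No
P18,VIM,2,2-3,0-1,2.6,21.0,17.5,16.7,Yes,No
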