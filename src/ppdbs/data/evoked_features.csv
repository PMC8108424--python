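id,target,trajectory,r1_peak_amp_mv,r1_peak_lat_ms,r1_trough_amp_mv,r1_trough_lat_ms,arp_ms,rrp_ms,erna_amp_mv,erna_lat_ms
P01,STN,1,2.19,0.28,0.61,0.67,0.56,2.36,0.16,4.30
P02,STN,2,1.04,0.33,0.86,0.75,0.64,2.76,0.20,4.39
P05,STN,1,3.58,0.58,Absent,Absent,0.60,2.44,0.72,4.34
P06,STN,1,1.14,0.29,0.26,0.72,0.64,2.56,0.17,3.76
P07,STN,1,1.90,0.27,Absent,Absent,0.50,2.88,0.24,4.59
P08,GPi,1,1.62,0.25,1.66,0.66,NA,NA,0.34,7.29
P10,GPi,1,0.86,0.20,0.39,0.58,NA,NA,0.15,3.39
P11,GPi,1,0.74,0.31,Absent,Absent,NA,NA,0.12,4.48
P12,GPi,1,0.97,0.36,0.40,0.65,0.47,1.70,0.10,3.96
P02,STN,1,2.49,0.35,1.00,1.00,0.68,3.62,Absent,Absent
P03,STN,1,0.07,0.28,0.03,0.67,0.40,2.36,Absent,Absent
P04,STN,1,0.12,0.31,0.03,0.72,0.48,2.36,Absent,Absent
P09,GPi,1,0.64,0.20,0.43,0.61,NA,NA,Absent,Absent
P13,VIM,1,1.69,0.35,1.21,0.81,0.56,2.40,Absent,Absent
P14,VIM,1,0.30,0.20,0.36,0.65,0.60,4.12,Absent,Absent
P14,VIM,2,0.26,0.17,0.35,0.62,0.68,6.12,Absent,Absent
P16,VIM,1,0.16,0.31,0.08,0.74,0.54,2.52,Absent,Absent
P17,VIM,1,0.73,0.33,0.57,0.73,0.60,2.76,Absent,Absent
P18,VIM,1,0.47,0.48,0.47,0.86,0.48,3.12,Absent,Absent
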