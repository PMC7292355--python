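drug,removal_2h,removal_4h,dd_human_lo,dd_human_hi,pbr_rat,pbr_human,vd_rat,vd_human_lo,vd_human_hi
AMK,27.1,46.8,53,53,0.8,0.5,0.71,0.35,0.39
AP,0,0,0,0,93.3,91.2,54.51,4.1,10.5
VCM,17.8,32.4,20.8,39.5,35.0,35.3,0.85,0.51,0.94
DRPM,16.1,29.6,46.3,56.1,26.1,2.5,0.37,0.30,0.40
VPA,8.4,15.9,15.1,21.9,24.4,38.9,0.46,0.1,0.4
APAP,6.1,11.8,10.8,10.8,25.7,24.0,2.21,3.18,3.18
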