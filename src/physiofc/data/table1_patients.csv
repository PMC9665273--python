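id,group,age,sex,usable_fmri,cardiac_present,resp_present,cardiac_noise,resp_noise,exclusion_note
P1,patient,19,F,Y,Y,Y,none,none,
P2,patient,37,M,Y,Y,Y,none,none,
P3,patient,61,M,Y,Y,Y,none,none,
P4,patient,29,M,Y,Y,Y,none,machine_noise,Poor quality of physiological data
P5,patient,20,M,Y,N,Y,,none,Incomplete physiological data
P6,patient,47,M,N,Y,Y,none,none,Failed brain segmentation
P8,patient,18,M,Y,Y,Y,none,none,
P9,patient,49,M,Y,Y,Y,none,none,
P10,patient,56,F,N,Y,Y,none,none,MR gadolinium contrast in BOLD data
P14,patient,34,M,N,Y,N,bad_position,,MR gadolinium contrast in BOLD data
P15,patient,73,F,Y,Y,Y,none,none,
P16,patient,72,M,Y,Y,Y,none,none,
P20,patient,66,F,Y,Y,Y,none,none,
P23,patient,78,M,Y,N,N,,,No physiological data acquisition
P24,patient,26,M,N,Y,Y,none,none,Failed brain segmentation
P26,patient,67,F,Y,Y,Y,motion,none,Poor quality of physiological data
P32,patient,26,M,Y,Y,Y,none,none,
P33,patient,73,M,Y,Y,Y,none,none,
P34,patient,34,M,Y,Y,Y,bad_position,none,Poor quality of physiological data
P36,patient,20,F,N,Y,Y,none,none,Failed brain segmentation
P37,patient,37,F,N,Y,Y,noisy,none,Signal void due to shunt in the right hemisphere
P38,patient,56,M,Y,N,N,,,No physiological data acquisition
P39,patient,34,F,N,Y,Y,none,motion,Signal void due to shunt in the right hemisphere
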