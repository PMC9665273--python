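id,group,age,sex,usable_fmri,cardiac_present,resp_present,cardiac_noise,resp_noise,exclusion_note
C1,control,33,F,Y,Y,Y,none,none,
C2,control,32,M,Y,Y,Y,none,none,
C3,control,48,F,Y,Y,Y,intermittent_loss,none,Poor quality of physiological data
C4,control,29,M,Y,Y,Y,none,none,
C5,control,30,F,Y,Y,Y,none,none,
C6,control,38,F,Y,Y,Y,none,none,
C7,control,28,F,Y,Y,Y,none,none,
C8,control,35,F,Y,Y,Y,none,none,
C12,control,24,F,Y,N,Y,,none,Incomplete physiological data
C13,control,28,F,Y,Y,Y,none,none,
C14,control,38,F,Y,Y,Y,none,none,
C15,control,35,M,Y,Y,Y,none,none,
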