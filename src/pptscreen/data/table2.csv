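category,fish_group,n,n_ppt,n_ph
I,A,9,2,0
I,B,32,0,0
I,C,25,2,2
I,D,26,5,2
I,E,1,0,0
II,A,5,5,3
II,B,0,0,0
II,C,3,3,3
II,D,3,3,3
II,E,1,1,1
III,A,2,2,1
III,B,0,0,0
III,C,2,0,0
III,D,0,0,0
III,E,0,0,0
IV,A,4,4,2
IV,B,3,1,0
IV,C,3,3,1
IV,D,3,2,1
IV,E,2,2,1
V,A,25,2,1
V,B,8,1,0
V,C,20,0,0
V,D,24,0,0
V,E,1,0,0
VI,A,9,2,0
VI,B,11,1,1
VI,C,10,1,1
VI,D,14,2,0
VI,E,2,0,0
VII,A,23,2,2
VII,B,19,0,0
VII,C,27,7,2
VII,D,31,2,2
VII,E,3,1,0
VIII,A,15,3,3
VIII,B,12,1,1
VIII,C,18,1,1
VIII,D,16,2,1
VIII,E,0,0,0
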