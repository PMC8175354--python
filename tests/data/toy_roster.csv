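id,group,gender,wave1,wave2
s1,A,girl,1,1
s2,A,boy,1,1
s3,A,girl,1,1
s4,B,boy,1,1
s5,B,girl,1,1
s6,B,boy,1,1
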