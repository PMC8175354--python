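ego,alter,wave,sign,intensity
s1,s2,1,positive,1
s1,s2,1,positive,2
s2,s3,1,positive,2
s2,s3,1,negative,2
s3,s4,1,positive,1
s3,s4,1,negative,2
s4,s5,1,negative,1
s4,s5,1,negative,2
s5,s6,1,positive,2
s6,s5,1,negative,1
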