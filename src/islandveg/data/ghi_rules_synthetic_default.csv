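category,t1,t2,t3
A,dead,dead,dead
A,-2,dead,dead
A,-2,-2,dead
A,-2,-2,-2
B,X,-2,dead
B,X,-2,-2
B,+1,-2,dead
B,+1,-1,-2
B,+2,-2,dead
B,+2,-1,-2
C,+1,+1,-2
C,+1,+1,-1
C,+2,+1,-1
C,+2,+2,-2
C,+2,+2,-1
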