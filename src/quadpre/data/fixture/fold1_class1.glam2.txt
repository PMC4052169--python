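>motif1
T
V
N
Q
I
T
E
L
>motif2
T
V
N
Q
I
T
E
L
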