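# columns: A R N D C Q E G H I L K M F P S T W Y V -
0.007000 0.007000 0.007000 0.007000 0.007000 0.007000 0.007000 0.007000 0.007000 0.007000 0.007000 0.007000 0.007000 0.007000 0.007000 0.007000 0.860000 0.007000 0.007000 0.007000 0.007000
0.007000 0.007000 0.007000 0.007000 0.007000 0.007000 0.007000 0.007000 0.007000 0.007000 0.007000 0.007000 0.007000 0.007000 0.007000 0.007000 0.007000 0.007000 0.007000 0.860000 0.007000
0.007000 0.007000 0.860000 0.007000 0.007000 0.007000 0.007000 0.007000 0.007000 0.007000 0.007000 0.007000 0.007000 0.007000 0.007000 0.007000 0.007000 0.007000 0.007000 0.007000 0.007000
0.007000 0.007000 0.007000 0.007000 0.007000 0.860000 0.007000 0.007000 0.007000 0.007000 0.007000 0.007000 0.007000 0.007000 0.007000 0.007000 0.007000 0.007000 0.007000 0.007000 0.007000
0.007000 0.007000 0.007000 0.007000 0.007000 0.007000 0.007000 0.007000 0.007000 0.860000 0.007000 0.007000 0.007000 0.007000 0.007000 0.007000 0.007000 0.007000 0.007000 0.007000 0.007000
0.007000 0.007000 0.007000 0.007000 0.007000 0.007000 0.007000 0.007000 0.007000 0.007000 0.007000 0.007000 0.007000 0.007000 0.007000 0.007000 0.860000 0.007000 0.007000 0.007000 0.007000
0.007000 0.007000 0.007000 0.007000 0.007000 0.007000 0.860000 0.007000 0.007000 0.007000 0.007000 0.007000 0.007000 0.007000 0.007000 0.007000 0.007000 0.007000 0.007000 0.007000 0.007000
0.007000 0.007000 0.007000 0.007000 0.007000 0.007000 0.007000 0.007000 0.007000 0.007000 0.860000 0.007000 0.007000 0.007000 0.007000 0.007000 0.007000 0.007000 0.007000 0.007000 0.007000
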