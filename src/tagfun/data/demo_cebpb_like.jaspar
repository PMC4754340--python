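>demo_cebpb_like synthetic CEBP-family-style demo matrix (not a database motif)
A [  2  1  1  2  1  2 18 17 ]
C [  1  2  2 14  2 13  1  1 ]
G [  1  1 15  2 14  3  0  1 ]
T [ 16 16  2  2  3  2  1  1 ]
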