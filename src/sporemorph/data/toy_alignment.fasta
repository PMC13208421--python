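>seq1 toy aligned sequence
AAAAA
>seq2 toy aligned sequence
AAAAR
>seq3 toy aligned sequence
AACCC
>seq4 toy aligned sequence
ACC-C
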