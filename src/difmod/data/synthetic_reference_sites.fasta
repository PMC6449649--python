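>CD synthetic XerC/XerD reference pdif site (28 bp, 11-6-11)
ATTTCGCATAAGTTGTATTATGTTAAAT
>DC synthetic XerD/XerC reference pdif site (28 bp, 11-6-11)
ATTTAACATAATCCAACTTATGCTAAAT
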