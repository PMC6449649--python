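>dif1 synthetic Proteobacteria-consensus-style chromosomal dif1 (28 bp)
GGTGCGCATAATGTATATTATGTTAAAT
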