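compound,mutant,fold_reduction
37,L91(3.33)A,58
37,L246(6.51)A,22
39,L91(3.33)A,97
39,L246(6.51)A,115
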