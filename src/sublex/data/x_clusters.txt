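# Phoneme clusters a letter-X grapheme may represent (one per line,
# phonemes space-separated). X is the only grapheme mapped to two phonemes.
k s
g z
k ʃ
g ʒ
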