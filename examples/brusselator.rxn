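(alpha) -> X : chi
(beta) + X -> Y : delta
2 X + Y -> 3 X : gamma
X -> EMPTY : xi
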