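(A) + X -> 2 X : alpha
X + Y -> 2 Y : beta
Y -> EMPTY : gamma
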