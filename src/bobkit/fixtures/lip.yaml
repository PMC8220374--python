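foot_length: 0.23
g: 9.81
kind: LIP
standing_com_height: 1.12
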