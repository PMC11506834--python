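# shoulder extended backward, elbow inverted
fixture: upper_limb_analog
ELV: 0.0
ELW: 60.0
SHU: 0.0
SHV: 40.0
SHW: 0.0
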