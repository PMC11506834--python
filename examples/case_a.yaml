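# shoulder forward-flexed, elbow extended
fixture: upper_limb_analog
ELV: 0.0
ELW: 0.0
SHU: 0.0
SHV: -90.0
SHW: 0.0
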