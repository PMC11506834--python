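# shoulder externally rotated (clamped to the joint stop), elbow flexed
fixture: upper_limb_analog
ELV: -90.0
ELW: 0.0
SHU: 90.0
SHV: 0.0
SHW: 0.0
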