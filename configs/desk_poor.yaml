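# Minutes-scale reduced protocol used for local validation.
profile: desk
preset: poor
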