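# Headline protocol, polymer-solvent attraction model (E_PS = -1, chi/z < 0).
# Week-scale per state point on one CPU.
profile: paper
preset: good
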