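# Headline protocol, polymer-polymer / solvent-solvent attraction model
# (E_PP = E_SS = -1, chi/z > 0). Week-scale per state point on one CPU:
# run on a workstation or cluster, never in the routine test suite.
profile: paper
preset: poor
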