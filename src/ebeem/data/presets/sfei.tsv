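# Historical/Modern Baylands categories -> regional lost/retained
diked	lost
filled bayland	lost
hillslope	lost
muted tidal bayland	lost
undefined	lost
alluvial plain	retained
deep bay	retained
fully tidal	retained
fully tidal bayland	retained
shallow bay	retained
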