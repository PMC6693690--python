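# Lower Columbia tidal-restriction categories -> regional lost/retained
unrestricted tidal	retained
partially restricted tidal	retained
significantly restricted tidal	lost
completely blocked	lost
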