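# Anthropogenic Impact modifier: AI07 marks diked areas; absence means retained
ai07	lost
*	retained
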