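comparison,agree_lost_ha,agree_retained_ha,disagree_region_lost_ha,disagree_region_retained_ha,unclassified_local_ha
Columbia River,21817,8552,1849,232,6723
San Francisco Bay,59261,11505,1764,1507,0
Oregon Coastal estuaries,17220,9357,5342,414,0
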