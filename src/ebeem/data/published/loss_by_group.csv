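grouping,group,n_estuaries,lost_ha,historical_ha
ecoregion,Salish Sea,13,25931,30448
ecoregion,"WA, OR, N. CA",26,60107,88164
ecoregion,Central CA,9,213882,233271
ecoregion,S. CA Bight,7,1965,3347
phys_type,Embayment/Bay,20,72865,88870
phys_type,Major river delta,9,171662,180856
phys_type,Riverine estuary,26,57358,85505
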