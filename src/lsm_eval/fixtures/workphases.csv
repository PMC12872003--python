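sub_district,phase,workers,days
Nkwantanang,mapping,2,1
Nkwantanang,spraying,3,1
Abaam,mapping,2,1
Abaam,spraying,3,1
Takyiman,mapping,2,1
Takyiman,spraying,3,1
Asuom,mapping,2,3
Asuom,spraying,3,2
Abodom,combined,6,2
Subi,combined,6,1
Pramkese,combined,6,2
Kade,combined,8,6
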