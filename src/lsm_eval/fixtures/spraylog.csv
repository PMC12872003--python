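sub_district,found_sites,sprayed_sites,packs_per_month
Nkwantanang,131,73,0.5
Abaam,154,91,0.5
Takyiman,119,89,0.5
Asuom,290,170,1
Abodom,18,18,0.5
Subi,25,25,0.5
Pramkese,24,24,0.5
Kade,210,210,2
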