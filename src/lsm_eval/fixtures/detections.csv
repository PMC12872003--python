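sub_district,sites_drone,sites_manual
Nkwantanang,154,34
Abaam,131,31
Takyiman,119,65
Asuom,290,62
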