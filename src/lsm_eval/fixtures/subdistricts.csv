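name,arm,population,area_km2,lsm_start_month
Nkwantanang,intervention,5070,0.94,September
Abaam,intervention,7100,1.03,September
Takyiman,intervention,4999,1.77,September
Asuom,intervention,12308,4.01,September
Abodom,control,5265,0.98,July
Subi,control,2695,1.11,July
Pramkese,control,7016,1.55,July
Kade,control,25736,7.14,July
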