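country,care_level,severity,low_usd,high_usd
TZ,EECC,moderate,0.21,2.13
TZ,EECC,severe,2.445,13.455
TZ,EECC,critical,6.1075,42.2725
KE,EECC,moderate,1.18,2.54
KE,EECC,severe,6.015,13.065
KE,EECC,critical,10.18,22.10
TZ,ACC,severe,4.95,5.73
TZ,ACC,critical,47.81,121.03
KE,ACC,severe,7.30,10.48
KE,ACC,critical,11.71,155.39
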