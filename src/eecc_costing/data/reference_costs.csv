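country,care_level,severity,category,usd_per_day
TZ,EECC,moderate,hotel,0.01
TZ,EECC,moderate,staffing,0.86
TZ,EECC,moderate,oxygen,0.00
TZ,EECC,moderate,pharmaceuticals,0.00
TZ,EECC,moderate,nonpharma_capital,0.02
TZ,EECC,moderate,nonpharma_recurrent,0.00
TZ,EECC,moderate,ppe,0.12
TZ,EECC,moderate,diagnostics,0.00
TZ,EECC,severe,hotel,0.01
TZ,EECC,severe,staffing,3.35
TZ,EECC,severe,oxygen,4.74
TZ,EECC,severe,pharmaceuticals,1.70
TZ,EECC,severe,nonpharma_capital,0.13
TZ,EECC,severe,nonpharma_recurrent,0.66
TZ,EECC,severe,ppe,0.24
TZ,EECC,severe,diagnostics,0.00
TZ,EECC,critical,hotel,0.01
TZ,EECC,critical,staffing,6.11
TZ,EECC,critical,oxygen,19.67
TZ,EECC,critical,pharmaceuticals,4.71
TZ,EECC,critical,nonpharma_capital,0.15
TZ,EECC,critical,nonpharma_recurrent,1.62
TZ,EECC,critical,ppe,0.57
TZ,EECC,critical,diagnostics,0.00
KE,EECC,moderate,hotel,0.06
KE,EECC,moderate,staffing,1.54
KE,EECC,moderate,oxygen,0.00
KE,EECC,moderate,pharmaceuticals,0.00
KE,EECC,moderate,nonpharma_capital,0.02
KE,EECC,moderate,nonpharma_recurrent,0.00
KE,EECC,moderate,ppe,0.13
KE,EECC,moderate,diagnostics,0.00
KE,EECC,severe,hotel,0.08
KE,EECC,severe,staffing,8.01
KE,EECC,severe,oxygen,4.74
KE,EECC,severe,pharmaceuticals,0.54
KE,EECC,severe,nonpharma_capital,0.15
KE,EECC,severe,nonpharma_recurrent,1.16
KE,EECC,severe,ppe,0.18
KE,EECC,severe,diagnostics,0.00
KE,EECC,critical,hotel,0.09
KE,EECC,critical,staffing,13.55
KE,EECC,critical,oxygen,19.68
KE,EECC,critical,pharmaceuticals,0.72
KE,EECC,critical,nonpharma_capital,0.15
KE,EECC,critical,nonpharma_recurrent,2.73
KE,EECC,critical,ppe,0.52
KE,EECC,critical,diagnostics,0.00
TZ,ACC,severe,hotel,0.01
TZ,ACC,severe,staffing,5.63
TZ,ACC,severe,oxygen,4.74
TZ,ACC,severe,pharmaceuticals,1.70
TZ,ACC,severe,nonpharma_capital,0.13
TZ,ACC,severe,nonpharma_recurrent,0.66
TZ,ACC,severe,ppe,0.24
TZ,ACC,severe,diagnostics,0.00
TZ,ACC,critical,hotel,2.90
TZ,ACC,critical,staffing,83.72
TZ,ACC,critical,oxygen,36.17
TZ,ACC,critical,pharmaceuticals,113.40
TZ,ACC,critical,nonpharma_capital,19.45
TZ,ACC,critical,nonpharma_recurrent,29.15
TZ,ACC,critical,ppe,1.68
TZ,ACC,critical,diagnostics,10.83
KE,ACC,severe,hotel,0.08
KE,ACC,severe,staffing,10.48
KE,ACC,severe,oxygen,4.74
KE,ACC,severe,pharmaceuticals,0.54
KE,ACC,severe,nonpharma_capital,0.15
KE,ACC,severe,nonpharma_recurrent,1.16
KE,ACC,severe,ppe,0.18
KE,ACC,severe,diagnostics,0.00
KE,ACC,critical,hotel,24.73
KE,ACC,critical,staffing,134.19
KE,ACC,critical,oxygen,36.17
KE,ACC,critical,pharmaceuticals,112.46
KE,ACC,critical,nonpharma_capital,19.45
KE,ACC,critical,nonpharma_recurrent,30.25
KE,ACC,critical,ppe,1.14
KE,ACC,critical,diagnostics,11.25
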