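patient_id,gender,age_y,weight_kg,a0_gbq
IP1,f,44.7,85,3.55
IP2,f,65.3,72,3.51
IP3,f,24.9,67,3.55
IP4,f,28.6,78,3.57
IP5,f,55.2,46,3.43
IP6,f,21.0,115,3.52
IP7,f,54.7,70,3.72
IP8,f,48.8,60,3.65
IP9,f,45.1,108,3.50
IP10,f,44.6,77,3.56
IP11,m,59.9,80,3.58
IP12,f,26.2,85,3.56
IP13,m,36.3,96,3.60
IP14,f,38.9,68,3.91
IP15,m,54.7,94,3.52
IP16,f,63.8,85,3.60
IP17,m,19.8,82,3.66
IP18,f,59.2,96,3.60
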