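patient_id,c,se_c,alpha,se_alpha,k1,se_k1,k2,se_k2,n0,se_n0,r2,n_points,group,R,se_R
IP1,0.012,0.001,0.931,0.036,0.210,0.038,0.018,0.011,0.004,0.015,0.99,9,1,0.19,0.04
IP2,0.023,0.008,0.942,0.031,0.389,0.231,0.006,0.007,-0.005,0.080,0.91,9,1,0.19,0.01
IP3,0.023,0.005,0.945,0.020,0.324,0.156,0.006,0.005,0.015,0.060,0.96,9,1,0.23,0.15
IP4,0.071,0.014,0.980,0.006,1.330,0.302,0.017,0.008,0.003,0.030,0.99,9,2,0.12,0.03
IP5,0.028,0.009,0.986,0.017,0.499,0.226,0.000,0.011,-0.020,0.090,0.94,9,1,0.10,0.08
IP6,0.109,0.125,0.954,0.050,3.028,3.811,0.026,0.010,-0.009,0.044,0.98,8,2,0.43,0.32
IP7,0.024,0.017,0.943,0.057,0.554,0.596,0.016,0.028,-0.103,0.148,0.81,9,1,0.24,0.13
IP9,0.047,0.056,0.950,0.091,1.479,2.259,0.040,0.097,-0.029,0.098,0.84,8,2,0.16,0.03
IP13,0.044,0.031,0.959,0.027,1.262,0.993,0.006,0.005,-0.004,0.085,0.87,9,2,0.35,0.04
IP14,0.047,0.031,0.924,0.056,1.140,1.004,0.031,0.024,-0.042,0.091,0.92,9,2,0.27,0.08
IP15,0.019,0.006,0.979,0.061,0.193,0.102,0.000,0.030,0.018,0.083,0.85,9,1,0.19,0.08
IP16,0.021,0.005,0.958,0.011,0.451,0.178,0.000,0.003,-0.003,0.051,0.96,9,1,0.18,0.03
IP17,0.051,0.031,0.935,0.045,1.393,1.117,0.044,0.030,-0.049,0.050,0.95,9,2,0.18,0.11
IP18,0.020,0.006,1.000,0.020,0.217,0.077,,,-0.033,0.109,0.90,9,1,0.20,0.11
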