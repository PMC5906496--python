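reaction_id,tetrazine_id,k_obs_per_s,c_excess_M,c_limiting_M,k_per_M_s,provenance
1+11,tz1,0.003278,0.002081,0.000064,1.58,printed
2+11,tz2,0.002652,0.002096,0.00005,1.27,printed
3+11,tz3,0.00205,0.002051,0.000049,1.00,printed
4+11,tz4,0.007801,0.002015,0.00005,3.87,printed
5+11,tz5,0.002703,0.002081,0.000034,1.30,printed
6+11,tz6,0.005811,0.00196,0.000046,2.96,printed
7+11,tz7,0.009894,0.001933,0.000103,5.12,printed
8+11,tz8,0.03064,0.002096,0.00005,14.6,printed
9+11,tz9,0.00461,0.002813,0.000058,1.64,printed
10+11,tz10,0.004514,0.002224,0.000061,2.03,printed
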