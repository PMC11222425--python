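condition,metabolite_id,mean_mmol_per_g_dry_soil,sd_mmol_per_g_dry_soil
S-O-,glucose,0.023,0.003
S-O-,xylose,0.033,0.001
S-O-,mannose,0.008,0.001
S-O-,galacturonic_acid,0.015,0.003
S-O-,h2,0.096,0.005
S-O-,co2,0.44,0.02
S-O-,ch4,0.29,0.007
S-O-,h2s,0,0
S-O-,acetate,0.11,0.012
S-O-,lactate,0.01,0.002
S-O-,butyrate,0.02,0.002
S+O-,glucose,0.02,0.002
S+O-,xylose,0.023,0.004
S+O-,mannose,0.008,0.001
S+O-,galacturonic_acid,0.016,0.002
S+O-,h2,0.058,0.003
S+O-,co2,0.49,0.02
S+O-,ch4,0.079,0.006
S+O-,h2s,0.18,0.008
S+O-,acetate,0.21,0.013
S+O-,lactate,0.037,0.004
S+O-,butyrate,0.012,0.004
S-O+,glucose,0.02,0.001
S-O+,xylose,0.02,0.002
S-O+,mannose,0.011,0.001
S-O+,galacturonic_acid,0.019,0.001
S-O+,h2,0.044,0.009
S-O+,co2,0.75,0.008
S-O+,ch4,0.009,0.001
S-O+,h2s,0,0
S-O+,acetate,0.021,0.002
S-O+,lactate,0.012,0.002
S-O+,butyrate,0,0
S+O+,glucose,0.016,0.001
S+O+,xylose,0.02,0.001
S+O+,mannose,0.011,0.001
S+O+,galacturonic_acid,0.015,0.001
S+O+,h2,0.037,0.001
S+O+,co2,0.81,0.04
S+O+,ch4,0.008,0.001
S+O+,h2s,0.003,0.001
S+O+,acetate,0.022,0.004
S+O+,lactate,0.013,0.002
S+O+,butyrate,0,0
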