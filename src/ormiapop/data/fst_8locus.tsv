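label	Kauai	Oahu	Hilo	California	Arizona	Sonora	Oaxaca	Texas	Florida
Kauai	0	0.029	0.066	0.102	0.080	0.099	0.108	0.086	0.083
Oahu	0.029	0	0.056	0.089	0.084	0.087	0.090	0.093	0.091
Hilo	0.066	0.056	0	0.115	0.100	0.110	0.111	0.117	0.113
California	0.102	0.089	0.115	0	0.028	0.030	0.056	0.059	0.065
Arizona	0.080	0.084	0.100	0.028	0	0.008	0.023	0.035	0.038
Sonora	0.099	0.087	0.110	0.030	0.008	0	0.037	0.028	0.031
Oaxaca	0.108	0.090	0.111	0.056	0.023	0.037	0	0.027	0.024
Texas	0.086	0.093	0.117	0.059	0.035	0.028	0.027	0	0.006
Florida	0.083	0.091	0.113	0.065	0.038	0.031	0.024	0.006	0
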