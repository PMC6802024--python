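label	Kauai	Oahu	Hilo	California	Arizona	Sonora	Oaxaca	Texas	Florida
Kauai	0	0.027	0.057	0.092	0.071	0.105	0.109	0.091	0.087
Oahu	0.027	0	0.047	0.088	0.079	0.099	0.095	0.100	0.098
Hilo	0.057	0.047	0	0.114	0.097	0.124	0.118	0.127	0.122
California	0.092	0.088	0.114	0	0.024	0.034	0.049	0.055	0.060
Arizona	0.071	0.079	0.097	0.024	0	0.011	0.019	0.031	0.035
Sonora	0.105	0.099	0.124	0.034	0.011	0	0.032	0.026	0.026
Oaxaca	0.109	0.095	0.118	0.049	0.019	0.032	0	0.022	0.021
Texas	0.091	0.100	0.127	0.055	0.031	0.026	0.022	0	0.008
Florida	0.087	0.098	0.122	0.060	0.035	0.026	0.021	0.008	0
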