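label	Kauai	Oahu	Hilo	California	Arizona	Sonora	Oaxaca	Texas	Florida
Kauai	0	0.033	0.063	0.327	0.395	0.365	0.443	0.427	0.442
Oahu	0.033	0	0.055	0.299	0.378	0.359	0.451	0.450	0.451
Hilo	0.063	0.055	0	0.310	0.369	0.375	0.456	0.454	0.461
California	0.327	0.299	0.310	0	0.132	0.163	0.293	0.263	0.303
Arizona	0.395	0.378	0.369	0.132	0	0.089	0.197	0.171	0.190
Sonora	0.365	0.359	0.375	0.163	0.089	0	0.189	0.167	0.202
Oaxaca	0.443	0.451	0.456	0.293	0.197	0.189	0	0.205	0.211
Texas	0.427	0.450	0.454	0.263	0.171	0.167	0.205	0	0.058
Florida	0.442	0.451	0.461	0.303	0.190	0.202	0.211	0.058	0
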