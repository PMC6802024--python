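label	Kauai	Oahu	Hilo	California	Arizona	Sonora	Oaxaca	Texas	Florida
Kauai	0	0.044	0.096	0.263	0.282	0.290	0.327	0.331	0.337
Oahu	0.044	0	0.073	0.229	0.267	0.286	0.305	0.332	0.336
Hilo	0.096	0.073	0	0.279	0.291	0.344	0.365	0.394	0.388
California	0.263	0.229	0.279	0	0.088	0.127	0.235	0.231	0.273
Arizona	0.282	0.267	0.291	0.088	0	0.067	0.151	0.165	0.187
Sonora	0.290	0.286	0.344	0.127	0.067	0	0.169	0.149	0.167
Oaxaca	0.327	0.305	0.365	0.235	0.151	0.169	0	0.158	0.171
Texas	0.331	0.332	0.394	0.231	0.165	0.149	0.158	0	0.045
Florida	0.337	0.336	0.388	0.273	0.187	0.167	0.171	0.045	0
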