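# Approximate collection-site coordinates (decimal degrees) for the nine
# fly populations; used with haversine distances as an example geography.
population	lat	lon
Kauai	22.05	-159.50
Oahu	21.45	-158.00
Hilo	19.70	-155.10
California	34.10	-118.70
Arizona	34.90	-111.80
Sonora	27.00	-108.90
Oaxaca	17.15	-96.80
Texas	30.30	-97.70
Florida	29.65	-82.30
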