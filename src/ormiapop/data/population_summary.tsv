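# Reported per-population sample sizes, allele counts and heterozygosities
# for the nine fly populations (full 11-locus panel; *_8 columns are the
# reduced 8-locus panel excluding the three HWE-deviating loci).
population	n	total_alleles	total_alleles_8	h_exp	h_exp_8	h_obs	h_obs_8
Kauai	20	29	21	0.437	0.480	0.367	0.460
Oahu	28	31	22	0.438	0.479	0.367	0.450
Hilo	32	34	26	0.401	0.449	0.321	0.400
California	32	62	47	0.588	0.591	0.478	0.528
Arizona	57	95	71	0.667	0.665	0.612	0.625
Sonora	17	70	52	0.677	0.658	0.588	0.648
Oaxaca	13	70	53	0.724	0.723	0.607	0.604
Texas	35	91	67	0.714	0.709	0.604	0.636
Florida	40	95	70	0.741	0.730	0.638	0.693
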