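# Per-population confirmed cricket host assemblages.
# common_hosts = regularly used species; all_hosts = every confirmed host.
population	common_hosts	all_hosts
Kauai	T_oceanicus	T_oceanicus
Oahu	T_oceanicus	T_oceanicus
Hilo	T_oceanicus	T_oceanicus
California	G_lineaticeps;G_integer	G_saxatilis;G_lineaticeps;G_integer
Arizona	G_longicercus;G_staccato;G_regularis;G_armatus;G_cohni	G_personatus;G_vocalis;G_staccato;G_armatus;G_montis;G_longicercus;G_lightfooti;G_multipulsator;G_regularis;G_cohni
Sonora	G_staccato;G_regularis;G_armatus;G_cohni	G_staccato;G_regularis;G_armatus;G_cohni;G_multipulsator
Oaxaca	G_assimilis	G_assimilis
Texas	G_texensis	G_texensis;G_firmus;G_assimilis
Florida	G_rubens	G_rubens;G_firmus
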