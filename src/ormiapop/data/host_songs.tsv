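# Confirmed host-species song features. Printed ranges resolved to midpoints.
# duty_cycle is a SYNTHETIC proxy (pulse_rate x 15 ms nominal pulse length,
# capped at 0.95): the deposited per-species duty cycles are not bundled.
# For the complex two-part T. oceanicus song, pulse_rate / pulses_per_unit /
# chirps_per_trill describe the stutter-trill part and the intro_* fields the
# introductory trill part.
species	song_type	dominant_freq	pulse_rate	pulses_per_unit	duty_cycle	chirps_per_trill	intro_pulses_per_trill	intro_pulse_rate
G_rubens	trill	4.7	52.5	150	0.7875
G_firmus	chirp	4.2	16	4	0.24
G_texensis	trill	5.2	77.5	45	0.95
G_assimilis	chirp	3.7	85	7.5	0.95
G_personatus	chirp	4.0	57	7	0.855
G_vocalis	chirp	4.8	33	3.5	0.495
G_staccato	chirp	5.2	73	7	0.95
G_armatus	stutter-trill	3.6	58	2	0.87	17.5
G_montis	chirp	3.8	22	4.5	0.33
G_longicercus	chirp	4.5	10	5	0.15
G_lightfooti	chirp	4.5	20	5	0.30
G_multipulsator	chirp	4.1	70	14	0.95
G_regularis	trill	4.5	38	50	0.57
G_cohni	stutter-trill	4.8	25	5	0.375	3.5
G_saxatilis	chirp	4.1	20	3.5	0.30
G_lineaticeps	chirp	5.1	55	7	0.825
G_integer	stutter-trill	4.5	60	2.5	0.90	47.5
T_oceanicus	complex stutter-trill	4.6	24	2	0.36	9	7	14
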