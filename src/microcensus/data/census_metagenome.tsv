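environment	total_1e26	cells_cultured_species_to_genus	cells_uncultured_genus_to_class	cells_uncultured_phylum_plus
marine_sediment	2900	390	1921	590
soil	2560	454	1268	839
terrestrial_subsurface	2500	702	1211	587
seawater	1010	143	640	229
freshwater	1.3	0.143	0.832	0.325
plant_hosts	1	0.49	0.37	0.14
animal_hosts	0.2	0.098	0.074	0.028
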