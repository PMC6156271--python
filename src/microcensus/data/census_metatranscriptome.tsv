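environment	total_1e26	cells_cultured_species_to_genus	cells_uncultured_genus_to_class	cells_uncultured_phylum_plus
soil	2560	48.5	757.5	1753
terrestrial_subsurface	2500	45	597	1858
seawater	1010	36	389	587
freshwater	1.3	0.045	0.521	0.734
plant_hosts	1	0.18	0.33	0.49
animal_hosts	0.2	0.036	0.066	0.098
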