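environment	total_1e26	source
marine_sediment	2900	Kallmeyer et al. 2012 marine sediment cell inventory
soil	2560	Whitman et al. 1998 soil cell inventory
terrestrial_subsurface	2500	Whitman et al. 1998 terrestrial subsurface cell inventory
seawater	1010	Whitman et al. 1998 open-ocean cell inventory
freshwater	1.3	Whitman et al. 1998 freshwater cell inventory
plant_hosts	1	plant-host literature cell inventory
animal_hosts	0.2	animal-host literature cell inventory
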