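# 21 avian species: total interchromosomal changes involving macro- and
# microchromosomes, changes between microchromosomes only, and published haploid
# chromosome number ("?" where no karyotype has been published).
species	haploid_n	total_interchrom	micro_interchrom	micro_ids
adelie_penguin	48	6	0
american_crow	40	1	0
common_cuckoo	?	1	0
pekin_duck	40	0	0
little_egret	33	4	1
emperor_penguin	36	5	0
peregrine_falcon	25	6	4
zebra_finch	40	0	0
hoatzin	?	3	0
annas_hummingbird	37	0	0
crested_ibis	34	6	0
killdeer	38	1	0
golden_collared_manakin	?	0	0
medium_ground_finch	?	0	0
ostrich	40	11	0
budgerigar	29	11	2
rock_dove	40	1	0
chimney_swift	?	1	0
turkey	40	2	0
downy_woodpecker	?	4	1
chicken	39	0	0
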