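# Life-cycle length (days, published range) and mitochondrial minichromosome
# count for sucking lice.
# species<TAB>life_cycle_min_days<TAB>life_cycle_max_days<TAB>n_minichromosomes
Haematopinus_suis	29	48	9
Polyplax_spinulosa	25	28	11
Pthirus_pubis	16	25	14
Pediculus_humanus_humanus	13	20	20
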