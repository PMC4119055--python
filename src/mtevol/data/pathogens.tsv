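# Pangenome panel: human pathogens and genome counts used for the
# pairwise dN/dS (patho-pangenome) demonstration.
species	n_genomes
Acinetobacter baumannii	186
Staphylococcus aureus	438
Pseudomonas aeruginosa	47
Mycobacterium tuberculosis	75
Enterococcus faecalis	271
Enterococcus faecium	229
Helicobacter pylori	243
Salmonella enterica	393
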