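# Small end-to-end demonstration run: three clans of three protein
# families, a neutral-ish codon alignment, and planted composition and
# occupancy structure.  Any key omitted here keeps its default.
simulate.n_clans = 3
simulate.families_per_clan = 3
simulate.members_per_family = 8
simulate.profile_length = 150
simulate.shared_within_clan = 0.7
simulate.shared_between_clans = 0.0
simulate.mutation_rate = 0.05
codon.n_sequences = 12
codon.n_codons = 120
codon.omega = 0.5
codon.branch_length = 0.1
phylo.bootstrap = 100
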