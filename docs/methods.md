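# Methods

`mtevol` re-creates, on synthetic data, a family-level comparative analysis
of bacterial AdoMet-dependent RNA methyltransferases (MTases): how similar
the families are in sequence, how they cluster into lineages, how their
amino-acid composition tracks their substrate, how conserved they are
across phyla, and how their coding sequences evolve at the codon level.
This note records the models, the defaults and the numerical choices, and
what the synthetic generators do and do not emulate.

## Profile scanning and the Similarity Index

Each family alignment, after dropping columns whose gap fraction exceeds
`max_gap_fraction` (default 0.5), becomes a position-specific scoring
matrix (PSSM) in bits:

    score(column, aa) = log2( ((count + pc·bg[aa]) / (n_rows + pc)) / bg[aa] )

with Laplace-style pseudocount weight `pc` (default 1.0) spread according
to the background `bg` (default uniform 1/20; no background was mandated
by the source data, and a uniform prior keeps the bit scale simple).
Targets are scanned with a Smith–Waterman local dynamic program over the
position-specific scores using affine gaps: a gap of length g costs
`gap_open + (g−1)·gap_extend` bits, defaults 4 and 0.5 bits. Ambiguous
residues (X, B, Z, U, O, J) score 0 everywhere — background odds — and
gaps in targets are rejected. This is deliberately *not* a profile HMM:
insert-state transitions, Forward scores and E-value calibration are out
of scope; the scorer preserves exactly the three quantities the
Similarity Index needs (aligned target length Lt, profile length Lp, bit
score S).

Hits above the bit-score threshold (default 25) are ranked by the
normalized Similarity Index

    SI = log2((Lt / Lp) · S)

and banded: SI > 7.5 ortholog, 5.0 < SI ≤ 7.5 paralog, 2.5 ≤ SI ≤ 5.0
related, SI < 2.5 discard. The paralog band's upper edge is taken at 7.5
so the bands tile the line with no gap; boundary points fall to the
lower-named band. Note the banding is purely operational — no explicit
evolutionary model is behind the cutoffs.

## Family network and Markov Clustering

Families become nodes; a pair is joined when the best hit in *either*
direction reaches the SI threshold (default 2.5), weighted with that best
SI — profile-versus-sequence scoring is asymmetric, so the reciprocal
maximum is used. MCL runs on the column-stochastic weight matrix with
self-loops set to each node's maximum incident weight (a standard
regularization; isolated nodes get 1.0), expansion 2, inflation 2.0,
pruning below 1e-5, and stops when the largest entry change drops below
1e-6 or after 200 iterations (non-convergence is flagged, and the last
iterate is still read out). Clusters are read from attractor rows;
overlapping attractors resolve to the first in row order, and cluster ids
are renumbered by each cluster's alphabetically first member so output is
independent of node insertion order. Connectivity is plain degree,
tie-broken by node name.

## Composition statistics

Family composition vectors are pooled residue counts over members divided
by total standard residues (ambiguity codes excluded from numerator and
denominator; the division is exact rational arithmetic so rows sum to 1
exactly). Families are clustered on `log2(max(freq, floor))` with
complete linkage and Euclidean distance; `floor` defaults to 1e-4 because
log2 of an absent residue is otherwise undefined. Rows are pre-sorted by
family name before linkage so equal-distance merges resolve
deterministically.

Group differences use a per-residue one-way fixed-effects ANOVA across
the four substrate groups (16S, 23S, tRNA, non-RNA) with Bonferroni
correction over `n_tests = 20` (one test per residue); per-group means
are reported so the direction of an enrichment is visible. Groups with
zero within-variance are reported, not dropped. The choice of a
univariate test per residue (rather than a multivariate analysis) keeps
each residue's signal interpretable; compositional coupling between
residues is accepted as a limitation.

## Phylogenetic profiles and UPGMA

Occupancy fractions are banded wide ≥ 0.75, midlow [0.25, 0.75),
undetected < 0.25 — symmetric bands around the ~50% occupancy that
defines mid-low conservation; both thresholds are arguments. Family
relationships use `d = 1 − r` (Pearson on rows, range [0, 2]); rows with
zero variance are rejected by name since their correlation is undefined.
UPGMA is implemented directly: merge the closest pair, average distances
weighted by cluster size, place each merge at half the merge distance.
Equal-distance merges pick the lexicographically smallest sorted name
pair, making the tree byte-reproducible. Bootstrap support (default 100
replicates) resamples columns — characters, not taxa, as is standard for
character matrices — and counts recovery of each original clade as a
root-invariant bipartition; replicates that draw a constant row are
redrawn.

## Codon-level evolution (NG86)

Synonymous/non-synonymous counting follows Nei–Gojobori (1986) with the
SNAP calculator's conventions: single-nucleotide changes to stop codons
are excluded from the per-position site-count denominators; mutational
pathways through stops are excluded from pathway averaging (if all are
blocked the differences are classified directly and the pair flagged);
codons with a gap, ambiguity or stop in either sequence are skipped
entirely. Proportions convert to rates with Jukes–Cantor,
`d = −(3/4)·ln(1 − (4/3)p)`; p ≥ 3/4 is reported saturated (NaN), and
finite distances are capped at 10. ω = dN/dS is undefined (excluded from
means, counted) when dS = 0 or either rate is saturated — not infinity,
which would poison aggregates. Gene-level ω is the mean of per-pair
ratios, not the ratio of means; both conventions exist in the field, and
mean-of-ratios matches "averaged ω from the pairwise comparisons".
An optional transition-weighted site counting (`ts_weight > 1`) upweights
transitions in the site denominators for users who want an
Ina-style correction; the default (1.0) is plain NG86, and the
transitional share of observed differences is always reported so the
correction's input stays visible. The log2 dN–dS regression excludes
genes with zero rates (counts logged) rather than flooring them, and
skips groups with fewer than three usable genes.

Cumulative substitution profiles are running sums over codons of
pathway-averaged synonymous and non-synonymous differences, averaged over
*all* sequence pairs (no reference sequence is privileged); hotspot
windows are 1-based inclusive codon intervals, and the share of total
non-synonymous difference inside each window is emitted.

## Synthetic data: what it emulates, and what it does not

*Family sets.* Family consensus sequences share a controlled fraction of
identical columns: a scalar share gives one core block common to all
families; a share matrix is realized hierarchically (global core plus
per-clan cores) and must be nested — block designs, the case of interest,
always are. Members are the consensus with i.i.d. substitutions at
`mutation_rate` (default 0.05). This emulates graded ortholog/paralog/
related structure but not indels, domain shuffling or rate heterogeneity
across sites, so scan recovery on these sets is easier than on real
families.

*Codon alignments.* One stop-free random ancestor evolves along
independent branches (star topology — the simplest shape that yields the
pairwise comparisons a pangenome analysis makes; no tree inference is
involved). Poisson(branch_length · n_codons) point mutations are proposed
per branch, transitions κ-fold (default 2) more often than each
transversion. A proposal creating a stop is rejected; otherwise it fixes
with probability min(1, ω) if non-synonymous and min(1, 1/ω) if
synonymous, so the realized dN/dS tracks the planted ω on both sides of
1 (damping synonymous fixation is the standard way to realize positive
selection in an acceptance scheme). `branch_length` is expected
*proposals* per codon; realized substitution counts are lower wherever
selection rejects. No codon-usage bias, indels or rate variation beyond
the ω map are modeled.

*Presence matrices.* wide draws occupancy per phylum from [0.9, 1.0],
midlow from [0.3, 0.7], absent from [0, 0.05] — inside the categorization
bands by construction, so round-trip recovery measures the categorizer's
thresholds, not biological noise.

*Composition tables.* Frequencies are `background · 2^(shift + noise)`
renormalized, with N(0, noise_sd) per-residue noise (default 0.1 log2
units) around a fixed bacterial-proteome-like background. The planted
+1 log2 K/R enrichment in the RNA groups is the effect the power checks
target; 10 families per group matches the scale of the real family sets.

Because every generator plants its truth, passing tests demonstrate that
each analysis stage recovers the structure it is designed to detect at
the stated rates — not that the stages would perform identically on real
downloads, where alignment error, indels and phylogenetic correlation
among families add noise these simulations omit.

## Problem sizes and runtime choices

Recovery checks use 20 sequences × 300 codons with branch length 0.1 for
ω (planted 0.2 / 1.0 / 2.0, ordering required in ≥ 9/10 seeds), 3 blocks
× 8 nodes for MCL (within-weight 6, between 2.5, ARI ≥ 0.9), 10 families
per group for composition power, and 1,000 (500 in the acceptance
script) null tables for ANOVA calibration. These sizes give stable
rates on a single CPU in about a minute each.

## Known limitations

- The PSSM scorer is not HMMER3; absolute bit scores differ from hmmscan
  and the 25-bit threshold is calibrated only in the sense that it
  separates the planted families cleanly.
- MCL cluster boundaries depend on inflation; 2.0 is the conventional
  default, not a fitted value.
- The ANOVA treats families as independent; real families share ancestry.
- NG86 with JC correction underestimates rates at high divergence; pairs
  near saturation are flagged rather than rescued.
- UPGMA assumes a molecular clock (ultrametricity); it is used here as a
  descriptive clustering of profiles, not as phylogeny inference.
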