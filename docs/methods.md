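# Methods

## Scope and data model

The pipeline operates on per-genome gene sets: protein sequences for
coding genes and nucleotide sequences for rRNA/ITS genes, supplied as a
FASTA file plus a TSV gene table (gene id, genome id, type, strand,
1-based start). The gene table is the sole authority on gene types; no
annotation-format parsing is attempted, which keeps the input contract
small and testable. Sequences are stored in reading orientation; the
strand is metadata. Ambiguity characters are accepted but never count as
identity matches, and in distance computations their columns are
excluded. Distance analyses consume pre-aligned multi-FASTA; producing
the alignment (e.g. with mafft) is outside the pipeline.

## Pairwise alignment

All-against-all global alignment (Needleman–Wunsch, affine gaps) stands
in for an orthology-pipeline alignment stage. Defaults: BLOSUM62 with gap
open 11 / extend 1 for proteins; match +5 / mismatch −4, gap open 10 /
extend 1 for nucleotides. Identity is computed over gap-free aligned
columns only, so length differences (terminal gaps) do not dilute it —
the natural reading of "sequence identity" for near-identical paralogs.
The score thresholds used downstream (130 within genomes, 180 across)
are parameters of the method, not of a particular matrix; absolute score
scales differ between substitution matrices, so the thresholds should be
recalibrated if the matrix is changed. A score floor (default 100, always
clipped to the smallest downstream threshold) lets the all-against-all
stage skip traceback for pairs that cannot qualify; it is a reporting
cut, not a methodological one.

## Two-stage family detection

Stage 1 builds, per genome, a homology graph from hits with score ≥ 130
and identity ≥ 98% and takes connected components of size ≥ 2 as paralog
clusters. "Distance" throughout is 1 − identity. Edges whose distance
deviates from the cluster's mean edge distance by more than `k_sd` = 2
standard deviations are pruned and components recomputed; the 2-SD rule
is a deterministic concretization of removing edges that differ
"significantly" from the cluster mean, applied only to clusters of ≥ 3
members (for a pair the deviation is undefined). Size-1 remnants of
pruning revert to singleton status.

Stage 2 links clusters of different genomes when the number of
qualifying member-pair hits (score ≥ 180, identity ≥ 50%) reaches
0.8·n_i·n_j, compared as a real number — two 2-member clusters need all
4 hits, since 3 < 3.2. When a cluster links to several clusters of one
foreign genome, only its lowest-average-distance link survives; the rule
is enforced from both endpoints, and ties break lexicographically so the
outcome is order-independent. The density rule is evaluated before
conflict resolution. Homologous groups are the connected components of
the surviving cluster graph; group ids are assigned in the lexicographic
order of their smallest member, making all outputs invariant to input
gene order.

Finally, genes that never entered a cluster are attached as single
orthologs to the group of their best qualifying cross-genome hit
(highest score, then smallest distance, then group id). Attachment never
creates a new group, and a genome contributes at most one cluster per
group: if the genome already has a cluster there, the singleton stays
out; if several singletons of one genome point at the same group, only
the best-scoring one joins. rRNA genes travel through the same two
stages under nucleotide scoring, so rRNA operon copy numbers appear in
the same matrix as protein families.

## K80 distances

For aligned pairs, columns containing a gap or ambiguity in either
sequence are removed (pairwise deletion — matching per-pair distance
computation; a complete-deletion mode across all sequences is not
provided because the synthetic alignments are gap-free and real input
can be pre-filtered). With transition proportion P and transversion
proportion Q over the n remaining sites, d = −½ln(1−2P−Q) − ¼ln(1−2Q).
When either logarithm's argument is non-positive the pair is saturated:
a single pair raises an error, while whole-matrix construction flags the
entry (NaN) and excludes it from all means and resampling, so one
runaway pair cannot abort an analysis. Identical sequences return
exactly 0 without touching the logarithms.

d_W pools all matrix entries whose two copies share a genome; d_B pools
all entries spanning genomes. Pooling (rather than averaging per-genome
means first) weights every pair equally; with near-constant within-genome
distances the two conventions differ negligibly.

## The independent-entry bootstrap

Treating all C(n,2) entries of a distance matrix as independent
observations would overstate the information content, since each copy
participates in n−1 entries. The resampling therefore draws, per
replicate, a random maximal matching on the copy labels — entries added
in random order under the constraint that no label is used twice, until
no in-scope entry can be added — restricted to the within- or
between-genome entries. Each replicate's matching is bootstrap-resampled
with replacement to its own size and its mean recorded; the overall mean
of replicate means and the 2.5/97.5 percentiles over `n_rep` replicates
(default 10,000) give the reported d* and 95% CI. Percentile intervals
are used because no parametric form is assumed for the replicate-mean
distribution. Both layers can be toggled (`resample=False` drops the
bootstrap layer; `n_rep=0` reports observed means only). Pair lists are
enumerated in canonical label-sorted order, so results are reproducible
under a fixed seed and invariant to input label order. The default seed
is 42 and is always recorded in the output.

## Correlation screen

Differentiation groups are encoded ordinally, G0–G3 → 0–3, equally
spaced; applying Pearson's R to this encoding is a modeling convention
(treating group steps as equal), while Spearman's ρ needs only the
ordering. p-values are two-sided: Pearson via the exact t transform with
n−2 df, Spearman via the t approximation with average ranks for ties (an
exact permutation option exists for n ≤ 10). A family is flagged when
either p < 0.01; per-test flags are reported alongside. No
multiple-testing correction is applied by default — the screen mirrors a
per-family testing convention — but a Benjamini–Hochberg option is
available and can only remove, never add, flags. Constant-copy families
have undefined correlation and are excluded with a warning.

## Synthetic data

The generator emulates the data regime the analysis assumes, with every
planted quantity recorded:

* **Protein families** (default 20 over 12 genomes): each family has a
  random root; each genome's family ancestor receives an exact number of
  substitutions such that between-genome amino-acid identity is about
  exp(−`between_divergence`) (≈ 74% at the default 0.3 — comfortably
  above the 50% cross-genome threshold and far below the 98% within
  threshold). Within a genome, extra copies get exactly
  round((1−`within_identity`)·L) substitutions, so pairwise copy
  identity is ≥ 1−2(1−`within_identity`) by construction (98% at the
  0.99 default, never below the clustering threshold). Copy counts are
  drawn per genome from a group-dependent rule whose defaults rise with
  differentiation level (G0: {1,1,2} … G3: {3,4,4}), planting the
  monotone association the screen is meant to detect.
* **rRNA family**: one 16S-like nucleotide family; genome ancestors
  evolve from a root under the exact K80 transition probabilities along
  a star tree with tip branches of `between_divergence`/2, so expected
  pairwise distance equals `between_divergence`. Within-genome copies
  carry exact planted SNP counts drawn from `rrna_snp_choices`
  (default 0/0/1/1/2/4 — the low-heterogeneity regime where most copy
  pairs are identical and a few differ by 1–4 SNPs). Copy counts follow
  a deterministic rule 1/2/2/4 for G0/G1/G2/G3.
* **Decoys**: unrelated random proteins that must not join any family.

Protein "evolution" is direct amino-acid substitution at matched
identity rather than a codon model — sufficient for testing
identity-threshold behavior, not for inferring selection. Alignments are
emitted gap-free; the pipeline excludes gap columns anyway, so indel
realism buys nothing for these tests. What passing tests therefore show
is that the clustering, distance and correlation machinery is correct
under the assumed regime; they do not validate robustness to alignment
error, indels, horizontal transfer, or concerted evolution dynamics in
real genomes.

Identical seeds give byte-identical datasets; `SyntheticTruth` stores
the planted copy matrix, per-copy SNP counts, the realized mean
within-genome 16S distance, and the configured between-genome target.

## Problem sizes and numerical choices

The validation runs use deliberately moderate sizes: planted-recovery
scans 12 genomes × 20 families (~560 genes, ~150k scored pairs, ~30 s);
bootstrap calibration regenerates 200 datasets of 8 genomes with 400
replicates each; the null calibration permutes group labels 1000 times
over a 30-genome, ~30-family matrix; the study-regime 16S simulation
uses 22 genomes, 1325 sites and 10,000 bootstrap replicates. Ties in
cluster conflict resolution and singleton assignment break
lexicographically; all set iterations are sorted, so every output is
deterministic and order-invariant. Distances are written at 6 decimals,
which round-trips below the precision of any reported quantity.

## Known limitations

* Alignment scores are BLOSUM62-scaled, not PAM-series; on real
  proteomes the 130/180 cut-offs select somewhat different hit sets than
  the original scoring they parameterize, so absolute gene counts on
  real data are qualitative targets.
* The bootstrap treats one maximal matching per replicate as the unit of
  independence across the pooled matrix; per-species stratified sampling
  is not implemented.
* No phylogenetic correction in the correlation screen: shared ancestry
  inflates effective sample size, as it does in the convention the
  screen mirrors.
* Real-data reproduction of published 16S divergence values requires
  externally downloaded and aligned genomes (see
  `tests/test_acceptance.py::test_real_16s_divergence_and_snps`).
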