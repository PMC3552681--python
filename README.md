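# paraconserve

Detecting highly conserved gene-copy (paralog) families across bacterial
genomes, quantifying 16S rRNA divergence within and between genomes, and
testing whether gene copy numbers track an organism's level of cell
differentiation.

## The problem

Bacterial genomes often carry several near-identical copies of a gene —
most prominently the ribosomal RNA (rrn) operon, whose copy number varies
from 1 to ~15 across bacteria. Two questions arise for a phylum such as
the cyanobacteria, whose species range from simple unicells to
filamentous forms with terminally differentiated nitrogen-fixing cells
(heterocysts):

1. Which gene families are maintained as highly conserved multi-copy
   families, and do their copy numbers correlate with morphological
   complexity?
2. How strongly conserved are 16S rRNA copies *within* a genome compared
   with their divergence *between* species — i.e. is 16S intragenomic
   heterogeneity low enough for the gene to remain a reliable taxonomic
   marker?

## The methods

**Two-stage paralog clustering.** From all-against-all global pairwise
alignments (Needleman–Wunsch, BLOSUM62 for proteins), within-genome hits
with alignment score ≥ 130 and sequence identity ≥ 98% become edges of a
homology graph; connected components are paralog clusters, after pruning
edges whose distance deviates from the cluster mean by more than 2 SD.
Clusters are then linked across genomes when ≥ 0.8·n_i·n_j qualifying
hits (score ≥ 180, identity ≥ 50%) connect their members; conflicting
links into the same genome are resolved by lowest average distance, and
connected components of the cluster graph become homologous groups.
Unclustered single orthologs join the group of their best qualifying hit.
The result is a copy-number matrix (families × genomes).

**K80 distances and the independent-entry bootstrap.** For aligned rRNA
copies, pairwise distances follow the Kimura two-parameter model,

    d = −½ ln(1 − 2P − Q) − ¼ ln(1 − 2Q),

with P and Q the transition and transversion proportions over columns
free of gaps and ambiguities. Mean distances are pooled within genomes
(d_W, between paralogs) and between genomes (d_B, between orthologs).
Uncertainty comes from a two-layer resampling: each replicate draws a
random maximal set of matrix entries sharing no row or column (a maximal
matching, the proxy for independent observations), bootstrap-resamples
it, and records the mean; 2.5/97.5 percentiles over 10,000 replicates
give 95% confidence intervals.

**Copy number vs morphology.** Genomes carry an ordinal differentiation
group — G0 (none), G1 (circadian control only), G2 (reversible), G3
(terminal differentiation) — encoded 0–3. Each family's copy numbers are
tested against this encoding with Spearman's ρ and Pearson's R; families
with p < 0.01 under either test are flagged.

A synthetic-data generator (`paraconserve simulate`) plants conserved
families, rRNA copies with exact SNP counts, K80 between-genome
divergence, and a monotone copy-number/group association, and records the
ground truth, so every stage of the pipeline can be validated against
known answers.

## Worked example

Simulate 6 genomes (groups G0–G3) carrying 4 planted protein families
plus an rRNA operon family, then run the scan, distance and correlation
stages:

```
paraconserve simulate --config sim.yaml --seed 7 -o out/
paraconserve scan --genomes out/genes.fasta --table out/genes.tsv \
    --traits out/traits.tsv -o copies.tsv
paraconserve distances --aligned out/rrna_16S.aln.fasta \
    --genome-map out/genome_map.tsv --bootstrap 500 --seed 1 -o table2.tsv
paraconserve correlate --copies copies.tsv --traits out/traits.tsv -o corr.tsv
```

with `sim.yaml` setting `n_genomes: 6`, `n_families: 4`,
`protein_length: 100`, `seq_length: 600`, `n_decoys: 2`. The copy-number
matrix (`copies.tsv`) reproduces the planted counts exactly, e.g.

```
gene_family  g01  g02  g03  g04  g05  g06
HG0003         1    2    2    2    2    4
HG0005         1    1    1    2    2    4
```

`table2.tsv` shows within-genome 16S divergence an order of magnitude
below between-genome divergence (the generator's target was 0.3):

```
scope    observed_mean  boot_mean  ci_lower  ci_upper  n_rep
within   0.00553        0.00479    0.00180   0.00783   500
between  0.30651        0.30854    0.28993   0.32684   500
```

and `corr.tsv` ranks families by ρ; the family with copies 1/2/2/2/2/4
rising across groups reaches R = 0.92 (p = 0.0095, flagged significant at
α = 0.01), while at n = 6 genomes the remaining families stay above the
threshold — with realistic genome counts (≥ 20) the planted monotone
families are flagged reliably.

The package also bundles the published 16S copy-number survey of 22
fully sequenced cyanobacterial genomes
(`paraconserve.datasets.cyanobacteria_16s()`): encoding its groups
(5× G0, 12× G1, 1× G2, 4× G3) and correlating them with the 48 16S
copies gives ρ = 0.74 and R = 0.86 (both p < 0.01).

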