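"""Synthetic genomes with planted conserved families and known ground truth.

The generator emulates the statistical regime the analysis assumes: a set
of bacterial genomes, each carrying

* ``n_families`` protein-coding families whose copy number per genome is
  drawn from a group-dependent rule (more copies in more differentiated
  groups -- the planted monotone association),
* one ribosomal-RNA-like nucleotide family ("rrn_16S") whose copy number
  follows its own group rule and whose within-genome copies differ by
  exact, planted SNP counts (the paper-like 0-4 SNP regime),
* a few unrelated decoy genes per genome.

Protein copies inside a genome are diverged to ``within_identity`` by
planting an exact number of substitutions; genomes diverge from a common
family ancestor so that between-genome amino-acid identity is about
exp(-between_divergence) (roughly 60-80% for the default 0.3).  rRNA
sequences evolve between genomes under the K80 substitution process along
a star tree with tip branches of ``between_divergence / 2``, so the
expected pairwise distance equals ``between_divergence``.

Everything planted is recorded in :class:`SyntheticTruth`, and identical
seeds give byte-identical output.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import seqio
from .distances import k80_distance
from .seqio import GeneRecord, GeneType, GenomeRecord, Strand

_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
_NT = np.array(list("AGCT"))  # order matters: index^1 is the transition partner
_DEFAULT_GROUP_CYCLE = ("G0", "G1", "G1", "G1", "G2", "G3")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    ``copy_number_rule`` maps each group to the support of a uniform copy
    count draw for protein families; ``rrna_copy_rule`` does the same for
    the rRNA family (deterministic by default: 1/2/2/4 copies for
    G0/G1/G2/G3, echoing the observed pattern where only terminally
    differentiating genomes carry four rRNA operons).
    ``rrna_snp_choices`` is the support of the per-extra-copy planted SNP
    count.  ``between_divergence`` is the target pairwise K80 distance
    between genomes (substitutions/site).
    """

    n_genomes: int = 12
    group_assignment: tuple[str, ...] | None = None
    n_families: int = 20
    copy_number_rule: Mapping[str, tuple[int, ...]] = field(
        default_factory=lambda: {
            "G0": (1, 1, 2), "G1": (1, 2, 2), "G2": (2, 2, 3), "G3": (3, 4, 4)})
    rrna_copy_rule: Mapping[str, tuple[int, ...]] = field(
        default_factory=lambda: {
            "G0": (1,), "G1": (2,), "G2": (2,), "G3": (4,)})
    within_identity: float = 0.99
    between_divergence: float = 0.3
    kappa: float = 2.0
    seq_length: int = 1200
    protein_length: int = 120
    n_decoys: int = 3
    rrna_snp_choices: tuple[int, ...] = (0, 0, 1, 1, 2, 4)
    seed: int = 42

    def __post_init__(self):
        if not (0.0 < self.within_identity <= 1.0):
            raise ValueError("within_identity must be in (0, 1]")
        if self.between_divergence < 0:
            raise ValueError("between_divergence must be >= 0")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if self.n_genomes < 1 or self.seq_length < 1 or self.protein_length < 1:
            raise ValueError("sizes must be positive")
        if self.group_assignment is not None:
            if len(self.group_assignment) != self.n_genomes:
                raise ValueError("group_assignment length != n_genomes")
            bad = set(self.group_assignment) - set(seqio.GROUP_LABELS)
            if bad:
                raise ValueError(f"unknown groups {sorted(bad)}")

    def groups(self) -> tuple[str, ...]:
        if self.group_assignment is not None:
            return tuple(self.group_assignment)
        return tuple(_DEFAULT_GROUP_CYCLE[i % len(_DEFAULT_GROUP_CYCLE)]
                     for i in range(self.n_genomes))


@dataclass
class SyntheticTruth:
    """Planted ground truth, consistent with the emitted sequences."""

    copy_matrix: pd.DataFrame            # family x genome, planted counts
    rrna_snps: dict[str, int]            # copy label -> SNPs vs genome ancestor
    d_w_true: float                      # realized mean within-genome 16S distance
    d_b_target: float                    # configured between-genome divergence
    within_identity: float


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    genomes: list[GenomeRecord]
    rrna_alignment: list[tuple[str, str]]
    genome_of_copy: dict[str, str]
    traits: dict[str, str]
    truth: SyntheticTruth

    @property
    def genes(self) -> list[GeneRecord]:
        return [g for genome in self.genomes for g in genome.genes]


# ---------------------------------------------------------------------------
# Sequence evolution

def simulate_k80_evolution(
    ancestor: str,
    branch_length: float,
    kappa: float,
    rng: np.random.Generator,
) -> str:
    """Evolve a nucleotide sequence under the K80 process for a branch.

    ``branch_length`` is in expected substitutions/site; the transition
    rate is ``kappa`` times each per-type transversion rate.  Site
    categories are drawn from the exact K80 transition probabilities, so
    the expected K80 distance between input and output equals the branch
    length.
    """
    if branch_length < 0:
        raise ValueError("branch_length must be >= 0")
    code = np.full(256, -1, dtype=np.int8)
    for i, b in enumerate("AGCT"):
        code[ord(b)] = i
    raw = np.frombuffer(ancestor.upper().encode("ascii"), dtype=np.uint8)
    idx = code[raw].astype(np.int64)
    if (idx < 0).any():
        raise ValueError("ancestor contains non-ACGT characters")
    if branch_length == 0.0:
        return ancestor.upper()
    beta_t = branch_length / (kappa + 2.0)
    alpha_t = kappa * beta_t
    e4b = math.exp(-4.0 * beta_t)
    e2ab = math.exp(-2.0 * (alpha_t + beta_t))
    p_ts = 0.25 + 0.25 * e4b - 0.5 * e2ab
    p_tv_each = 0.25 - 0.25 * e4b
    u = rng.random(idx.size)
    out = idx.copy()
    # categories: [0, p_ts) transition; next two windows: the transversions
    ts_mask = u < p_ts
    tv1_mask = (~ts_mask) & (u < p_ts + p_tv_each)
    tv2_mask = (~ts_mask) & (~tv1_mask) & (u < p_ts + 2 * p_tv_each)
    # bases ordered A,G,C,T: i^1 = transition partner, i^2 and i^3 = transversions
    out[ts_mask] ^= 1
    out[tv1_mask] ^= 2
    out[tv2_mask] ^= 3
    return "".join(_NT[out])


def _random_seq(rng: np.random.Generator, length: int, alphabet: np.ndarray) -> str:
    return "".join(alphabet[rng.integers(0, alphabet.size, size=length)])


def _mutate_exact(seq: str, n_subs: int, rng: np.random.Generator,
                  alphabet: np.ndarray) -> str:
    """Substitute exactly ``n_subs`` distinct sites to different residues."""
    if n_subs == 0:
        return seq
    arr = np.array(list(seq))
    sites = rng.choice(arr.size, size=min(n_subs, arr.size), replace=False)
    for s in sites:
        choices = alphabet[alphabet != arr[s]]
        arr[s] = choices[rng.integers(0, choices.size)]
    return "".join(arr)


# ---------------------------------------------------------------------------
# Dataset assembly

def _protein_tip_subs(cfg: SimulationConfig) -> int:
    # per-tip substitution count giving pairwise identity ~ exp(-between_divergence)
    target = math.exp(-cfg.between_divergence)
    q = 1.0 - math.sqrt(target)
    return round(q * cfg.protein_length)


def generate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Generate one fully reproducible dataset with recorded ground truth."""
    rng = np.random.default_rng(config.seed)
    groups = config.groups()
    genome_ids = [f"g{i+1:02d}" for i in range(config.n_genomes)]
    traits = dict(zip(genome_ids, groups))

    genes_by_genome: dict[str, list[GeneRecord]] = {g: [] for g in genome_ids}
    next_pos = {g: 1 for g in genome_ids}
    copy_counts: dict[str, dict[str, int]] = {}

    def add_gene(genome_id, gene_id, gene_type, seq):
        strand = Strand.FORWARD if rng.random() < 0.5 else Strand.REVERSE
        genes_by_genome[genome_id].append(GeneRecord(
            gene_id=gene_id, genome_id=genome_id, gene_type=gene_type,
            strand=strand, start_pos=next_pos[genome_id], sequence=seq))
        next_pos[genome_id] += len(seq) + 100

    # protein families
    s_within = round((1.0 - config.within_identity) * config.protein_length)
    s_tip = _protein_tip_subs(config)
    for f in range(config.n_families):
        fam = f"fam{f+1:03d}"
        root = _random_seq(rng, config.protein_length, _AA)
        counts = {}
        for genome_id in genome_ids:
            ancestor = _mutate_exact(root, s_tip, rng, _AA)
            n_copies = int(rng.choice(config.copy_number_rule[traits[genome_id]]))
            counts[genome_id] = n_copies
            for k in range(n_copies):
                seq = ancestor if k == 0 else _mutate_exact(
                    ancestor, s_within, rng, _AA)
                add_gene(genome_id, f"{genome_id}|{fam}_{k+1}",
                         GeneType.PROTEIN, seq)
        copy_counts[fam] = counts

    # rRNA family: one 16S-like operon, K80 evolution between genomes,
    # exact planted SNP counts within
    rrna_root = _random_seq(rng, config.seq_length, _NT)
    rrna_alignment: list[tuple[str, str]] = []
    genome_of_copy: dict[str, str] = {}
    rrna_snps: dict[str, int] = {}
    rrna_counts = {}
    within_dists: list[float] = []
    for genome_id in genome_ids:
        ancestor = simulate_k80_evolution(
            rrna_root, config.between_divergence / 2.0, config.kappa, rng)
        n_copies = int(rng.choice(config.rrna_copy_rule[traits[genome_id]]))
        rrna_counts[genome_id] = n_copies
        copies = []
        for k in range(n_copies):
            if k == 0:
                seq, snps = ancestor, 0
            else:
                snps = int(rng.choice(config.rrna_snp_choices))
                seq = _mutate_exact(ancestor, snps, rng, _NT)
            label = f"{genome_id}|16S_{k+1}"
            copies.append(seq)
            rrna_alignment.append((label, seq))
            genome_of_copy[label] = genome_id
            rrna_snps[label] = snps
            add_gene(genome_id, label, GeneType.RRNA_16S, seq)
        for a in range(len(copies)):
            for b in range(a + 1, len(copies)):
                within_dists.append(k80_distance(copies[a], copies[b]))
    copy_counts["rrn_16S"] = rrna_counts

    # unrelated decoys
    for genome_id in genome_ids:
        for k in range(config.n_decoys):
            add_gene(genome_id, f"{genome_id}|decoy_{k+1}", GeneType.PROTEIN,
                     _random_seq(rng, config.protein_length, _AA))

    genomes = [GenomeRecord(genome_id=g, group=traits[g],
                            genes=genes_by_genome[g])
               for g in genome_ids]
    copy_matrix = pd.DataFrame.from_dict(
        copy_counts, orient="index", columns=genome_ids, dtype=int).sort_index()
    truth = SyntheticTruth(
        copy_matrix=copy_matrix,
        rrna_snps=rrna_snps,
        d_w_true=float(np.mean(within_dists)) if within_dists else float("nan"),
        d_b_target=config.between_divergence,
        within_identity=config.within_identity,
    )
    return SyntheticDataset(config=config, genomes=genomes,
                            rrna_alignment=rrna_alignment,
                            genome_of_copy=genome_of_copy,
                            traits=traits, truth=truth)


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Emit the dataset in the exact formats the pipeline consumes.

    Writes genes.fasta + genes.tsv (gene table), rrna_16S.aln.fasta,
    genome_map.tsv, traits.tsv and truth.json; returns the paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "genes.fasta",
        "table": outdir / "genes.tsv",
        "rrna": outdir / "rrna_16S.aln.fasta",
        "genome_map": outdir / "genome_map.tsv",
        "traits": outdir / "traits.tsv",
        "truth": outdir / "truth.json",
    }
    seqio.write_gene_table(dataset.genes, paths["table"], paths["fasta"])
    seqio.write_fasta(dataset.rrna_alignment, paths["rrna"])
    pd.DataFrame(
        {"label": list(dataset.genome_of_copy),
         "genome_id": list(dataset.genome_of_copy.values())}
    ).to_csv(paths["genome_map"], sep="\t", index=False)
    pd.DataFrame(
        {"genome_id": list(dataset.traits), "group": list(dataset.traits.values())}
    ).to_csv(paths["traits"], sep="\t", index=False)
    truth = {
        "copy_matrix": {fam: row.to_dict()
                        for fam, row in dataset.truth.copy_matrix.iterrows()},
        "rrna_snps": dataset.truth.rrna_snps,
        "d_w_true": dataset.truth.d_w_true,
        "d_b_target": dataset.truth.d_b_target,
        "within_identity": dataset.truth.within_identity,
        "seed": dataset.config.seed,
    }
    paths["truth"].write_text(json.dumps(truth, indent=2, sort_keys=True))
    return paths
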