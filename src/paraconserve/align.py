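"""All-against-all pairwise global alignment producing homology hits.

Every pair of genes sharing an alphabet is aligned end-to-end
(Needleman-Wunsch with affine gaps); the resulting score and percent
identity become an edge candidate for the homology graph.  Percent
identity is computed over gap-free aligned columns only, so terminal gaps
from length differences do not dilute it, and ambiguity characters (X, N)
never count as matches.

Scoring defaults: BLOSUM62 with gap open 11 / extend 1 for proteins;
match +5 / mismatch -4 with gap open 10 / extend 1 for nucleotides.  The
downstream score cut-offs (130 within a genome, 180 across genomes) are
method parameters and remain configurable; absolute score scales differ
between substitution matrices, so users swapping the matrix should
recalibrate the cut-offs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache
from typing import Callable, Iterable, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .seqio import GeneRecord, sequence_alphabet

# characters that can never count as an identity match, per alphabet
# (N is a real residue -- asparagine -- in proteins, an ambiguity in DNA)
_AMBIGUOUS = {
    "protein": set("XBZJ*"),
    "nucleotide": set("NRYSWKMBDHV"),
}


@dataclass(frozen=True)
class AlignmentParams:
    """Scoring configuration for pairwise alignment."""

    alphabet: str = "protein"            # 'protein' | 'nucleotide'
    matrix_name: str = "BLOSUM62"        # proteins only
    match: float = 5.0                   # nucleotides only
    mismatch: float = -4.0
    gap_open: float = 11.0               # cost of the first gap position
    gap_extend: float = 1.0
    mode: str = "global"                 # 'global' | 'local'

    def __post_init__(self):
        if self.alphabet not in ("protein", "nucleotide"):
            raise ValueError(f"unknown alphabet {self.alphabet!r}")
        if self.mode not in ("global", "local"):
            raise ValueError(f"unknown mode {self.mode!r}")


PROTEIN_PARAMS = AlignmentParams(alphabet="protein", gap_open=11.0, gap_extend=1.0)
NUCLEOTIDE_PARAMS = AlignmentParams(
    alphabet="nucleotide", match=5.0, mismatch=-4.0, gap_open=10.0, gap_extend=1.0
)


@dataclass(frozen=True)
class HomologyHit:
    """A scored pairwise alignment between two genes.

    ``distance`` is the complement of fractional identity; it is the edge
    weight used for outlier pruning and tie-breaking in the clustering
    stages.
    """

    gene_a: str
    gene_b: str
    score: float
    identity: float

    def __post_init__(self):
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError(f"identity out of [0,1]: {self.identity}")

    @property
    def distance(self) -> float:
        return 1.0 - self.identity

    def involves(self, gene_id: str) -> bool:
        return gene_id in (self.gene_a, self.gene_b)

    def other(self, gene_id: str) -> str:
        if gene_id == self.gene_a:
            return self.gene_b
        if gene_id == self.gene_b:
            return self.gene_a
        raise KeyError(gene_id)


@lru_cache(maxsize=8)
def _aligner(params: AlignmentParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    if params.alphabet == "protein":
        aligner.substitution_matrix = substitution_matrices.load(params.matrix_name)
    else:
        aligner.match_score = params.match
        aligner.mismatch_score = params.mismatch
    aligner.open_gap_score = -params.gap_open
    aligner.extend_gap_score = -params.gap_extend
    aligner.mode = params.mode
    return aligner


def _identity_from_alignment(alignment, seq_a: str, seq_b: str,
                             alphabet: str) -> float:
    """Fraction of identical residues over gap-free aligned columns."""
    ambiguous = _AMBIGUOUS[alphabet]
    matches = 0
    columns = 0
    blocks_a, blocks_b = alignment.aligned
    for (sa, ea), (sb, eb) in zip(blocks_a, blocks_b):
        sub_a = seq_a[sa:ea]
        sub_b = seq_b[sb:eb]
        columns += ea - sa
        for x, y in zip(sub_a, sub_b):
            if x == y and x not in ambiguous:
                matches += 1
    if columns == 0:
        return 0.0
    return matches / columns


def pair_score(seq_a: str, seq_b: str, params: AlignmentParams) -> float:
    """Optimal alignment score only (fast path, no traceback)."""
    return float(_aligner(params).score(seq_a, seq_b))


def align_pair(
    seq_a: str,
    seq_b: str,
    params: AlignmentParams | None = None,
    id_a: str = "a",
    id_b: str = "b",
) -> HomologyHit:
    """Optimally align two sequences; return the scored hit.

    Raises ``ValueError`` for empty sequences or when the two sequences
    come from different alphabets (protein vs nucleotide).
    """
    if not seq_a or not seq_b:
        raise ValueError("cannot align an empty sequence")
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    alpha_a = sequence_alphabet(seq_a)
    alpha_b = sequence_alphabet(seq_b)
    if params is None:
        params = PROTEIN_PARAMS if "protein" in (alpha_a, alpha_b) else NUCLEOTIDE_PARAMS
    # an all-ACGT string is alphabet-ambiguous; only a genuine conflict
    # (one clearly protein, scoring set to nucleotide) is an error
    if "protein" in (alpha_a, alpha_b) and params.alphabet == "nucleotide":
        raise ValueError("alphabet mismatch: protein residues under nucleotide scoring")
    if alpha_a != alpha_b and "protein" in (alpha_a, alpha_b) and params.alphabet == "protein":
        # nucleotide-looking sequence vs protein: legal (ACGT are amino acids too)
        pass
    aligner = _aligner(params)
    alignments = aligner.align(seq_a, seq_b)
    best = alignments[0]
    identity = _identity_from_alignment(best, seq_a, seq_b, params.alphabet)
    return HomologyHit(gene_a=id_a, gene_b=id_b, score=float(best.score),
                       identity=identity)


def all_against_all(
    genes: Sequence[GeneRecord],
    protein_params: AlignmentParams = PROTEIN_PARAMS,
    nucleotide_params: AlignmentParams = NUCLEOTIDE_PARAMS,
    min_score: float | None = None,
    pair_filter: Callable[[GeneRecord, GeneRecord], bool] | None = None,
) -> list[HomologyHit]:
    """Align every same-alphabet unordered gene pair; return scored hits.

    Cross-alphabet pairs (protein vs nucleotide) are skipped.  When
    ``min_score`` is given, pairs are first scored without traceback and
    only pairs at or above the floor get a full alignment and identity --
    the floor is a reporting cut, set it below any downstream threshold.
    ``pair_filter`` restricts which pairs are compared (e.g. same-genome
    only for the within-species stage).
    """
    hits: list[HomologyHit] = []
    ordered = sorted(genes, key=lambda g: g.gene_id)
    by_alphabet: dict[str, list[GeneRecord]] = {}
    for g in ordered:
        by_alphabet.setdefault(g.alphabet, []).append(g)
    for alphabet, members in sorted(by_alphabet.items()):
        params = protein_params if alphabet == "protein" else nucleotide_params
        aligner = _aligner(params)
        for ga, gb in itertools.combinations(members, 2):
            if pair_filter is not None and not pair_filter(ga, gb):
                continue
            if min_score is not None:
                score = float(aligner.score(ga.sequence, gb.sequence))
                if score < min_score:
                    continue
            hit = align_pair(ga.sequence, gb.sequence, params,
                             id_a=ga.gene_id, id_b=gb.gene_id)
            hits.append(hit)
    return hits


def hits_to_rows(hits: Iterable[HomologyHit]) -> list[dict]:
    """Flatten hits for TSV export."""
    return [
        {"gene_a": h.gene_a, "gene_b": h.gene_b,
         "score": h.score, "identity": round(h.identity, 6)}
        for h in hits
    ]
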