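"""Sequence and table I/O: FASTA, gene tables, trait tables, distance matrices.

The pipeline's on-disk interface is deliberately plain: an (optionally
wrapped) FASTA file with one record per gene, a tab-separated gene table
naming each gene's genome, type, strand and 1-based start coordinate, a
trait table assigning each genome an ordinal differentiation group
(G0..G3), and TSV matrices.  The gene table is the single source of truth
for gene types; no annotation-file parsing happens here.
"""

from __future__ import annotations

import enum
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger("paraconserve")

GROUP_LABELS = ("G0", "G1", "G2", "G3")

# Residues tolerated per alphabet; ambiguity codes are accepted but flagged,
# and downstream they count as mismatches (identity) or excluded sites (K80).
_NUC_CHARS = set("ACGTU")
_NUC_AMBIG = set("NRYSWKMBDHV")
_PROT_CHARS = set("ACDEFGHIKLMNPQRSTVWY")
_PROT_AMBIG = set("XBZJUO*")
GAP_CHARS = set("-.")


class FormatError(ValueError):
    """Malformed input file (FASTA or table)."""


class GeneType(str, enum.Enum):
    PROTEIN = "protein"
    RRNA_16S = "rRNA_16S"
    RRNA_23S = "rRNA_23S"
    RRNA_5S = "rRNA_5S"
    ITS = "ITS"
    OTHER = "other"

    @property
    def is_protein(self) -> bool:
        return self is GeneType.PROTEIN


class Strand(str, enum.Enum):
    FORWARD = "forward"
    REVERSE = "reverse"

    @classmethod
    def parse(cls, value: str) -> "Strand":
        aliases = {
            "forward": cls.FORWARD, "f": cls.FORWARD, "+": cls.FORWARD,
            "reverse": cls.REVERSE, "r": cls.REVERSE, "-": cls.REVERSE,
        }
        try:
            return aliases[str(value).strip().lower()]
        except KeyError:
            raise ValueError(f"invalid strand value {value!r}") from None


def sequence_alphabet(sequence: str) -> str:
    """Classify a residue string as 'nucleotide' or 'protein'.

    A string whose letters all fall in the nucleotide alphabet (plus
    ambiguity and gap codes) is nucleotide; anything else is protein.
    """
    chars = set(sequence.upper()) - GAP_CHARS
    if not chars:
        raise ValueError("sequence contains no residues")
    if chars <= (_NUC_CHARS | _NUC_AMBIG):
        return "nucleotide"
    if chars <= (_PROT_CHARS | _PROT_AMBIG):
        return "protein"
    bad = chars - (_PROT_CHARS | _PROT_AMBIG)
    raise ValueError(f"unrecognized residue characters: {sorted(bad)}")


@dataclass(frozen=True)
class GeneRecord:
    """One gene: identity, provenance, type, coordinates and sequence.

    Sequences are stored in reading orientation; ``strand`` records which
    DNA strand the gene lies on but does not affect the stored residues.
    """

    gene_id: str
    genome_id: str
    gene_type: GeneType
    strand: Strand
    start_pos: int
    sequence: str

    def __post_init__(self):
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")
        if not self.sequence:
            raise ValueError(f"gene {self.gene_id}: empty sequence")
        if self.start_pos < 1:
            raise ValueError(f"gene {self.gene_id}: start_pos must be >= 1")
        object.__setattr__(self, "sequence", self.sequence.upper())
        alphabet = sequence_alphabet(self.sequence)
        expected = "protein" if self.gene_type.is_protein else "nucleotide"
        if alphabet != expected:
            # all-ACGT protein sequences are legal but indistinguishable;
            # only reject the impossible direction
            if expected == "nucleotide" and alphabet == "protein":
                raise ValueError(
                    f"gene {self.gene_id}: {self.gene_type.value} gene with "
                    f"non-nucleotide residues"
                )
        if self.has_ambiguity:
            log.debug("gene %s contains ambiguity characters", self.gene_id)

    @property
    def alphabet(self) -> str:
        return "protein" if self.gene_type.is_protein else "nucleotide"

    @property
    def has_ambiguity(self) -> bool:
        ambig = _PROT_AMBIG if self.gene_type.is_protein else _NUC_AMBIG
        return bool(set(self.sequence) & ambig)


@dataclass
class GenomeRecord:
    """A genome: identifier, ordinal differentiation group, and its genes."""

    genome_id: str
    group: str | None = None
    genes: list[GeneRecord] = field(default_factory=list)
    genome_size_mb: float | None = None

    def __post_init__(self):
        if self.group is not None and self.group not in GROUP_LABELS:
            raise ValueError(
                f"genome {self.genome_id}: group must be one of "
                f"{GROUP_LABELS} or None, got {self.group!r}"
            )
        for g in self.genes:
            if g.genome_id != self.genome_id:
                raise ValueError(
                    f"gene {g.gene_id} carries genome_id {g.genome_id!r}, "
                    f"expected {self.genome_id!r}"
                )
        if self.genome_size_mb is not None and self.genome_size_mb <= 0:
            raise ValueError("genome_size_mb must be positive")


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into ordered (id, sequence) pairs.

    Record ids are the first whitespace-delimited token of each header;
    sequences are upper-cased.  An empty file or a file that does not start
    with a header raises :class:`FormatError`.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise FormatError(f"{path}: empty FASTA file")
    if not text.lstrip().startswith(">"):
        raise FormatError(f"{path}: not a FASTA file (no '>' header)")
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"{path}: record {rec.id!r} has empty sequence")
        records.append((rec.id, seq))
    if not records:
        raise FormatError(f"{path}: no FASTA records")
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    """Write (id, sequence) pairs as wrapped FASTA."""
    seq_records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Gene table / trait table

GENE_TABLE_COLUMNS = ("gene_id", "genome_id", "gene_type", "strand", "start_pos")


def read_gene_table(table_path: str | Path, fasta_path: str | Path) -> list[GeneRecord]:
    """Join a TSV gene table with its companion FASTA into GeneRecords.

    Every ``gene_id`` in the table must appear in the FASTA; FASTA records
    absent from the table are reported (warning) and dropped.
    """
    df = pd.read_csv(table_path, sep="\t", comment="#", dtype=str)
    missing = set(GENE_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{table_path}: missing columns {sorted(missing)}")
    dup = df["gene_id"][df["gene_id"].duplicated()]
    if not dup.empty:
        raise FormatError(
            f"{table_path}: duplicate gene_id(s): {sorted(dup.unique())}"
        )
    seqs = dict(read_fasta(fasta_path))
    absent = [g for g in df["gene_id"] if g not in seqs]
    if absent:
        raise FormatError(
            f"{table_path}: gene_id(s) absent from FASTA: {absent[:10]}"
        )
    unmatched = set(seqs) - set(df["gene_id"])
    if unmatched:
        warnings.warn(
            f"{len(unmatched)} FASTA record(s) not listed in the gene table",
            stacklevel=2,
        )
    records = []
    for row in df.itertuples(index=False):
        records.append(
            GeneRecord(
                gene_id=row.gene_id,
                genome_id=row.genome_id,
                gene_type=GeneType(row.gene_type),
                strand=Strand.parse(row.strand),
                start_pos=int(row.start_pos),
                sequence=seqs[row.gene_id],
            )
        )
    return records


def write_gene_table(genes: Sequence[GeneRecord], table_path: str | Path,
                     fasta_path: str | Path) -> None:
    """Write GeneRecords as the TSV + FASTA pair :func:`read_gene_table` reads."""
    df = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "genome_id": [g.genome_id for g in genes],
            "gene_type": [g.gene_type.value for g in genes],
            "strand": [g.strand.value for g in genes],
            "start_pos": [g.start_pos for g in genes],
        }
    )
    df.to_csv(table_path, sep="\t", index=False)
    write_fasta([(g.gene_id, g.sequence) for g in genes], fasta_path)


def read_trait_table(path: str | Path) -> dict[str, str]:
    """Read a TSV mapping genome_id -> differentiation group (G0..G3)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if not {"genome_id", "group"} <= set(df.columns):
        raise FormatError(f"{path}: expected columns genome_id, group")
    traits = {}
    for row in df.itertuples(index=False):
        if row.group not in GROUP_LABELS:
            raise FormatError(
                f"{path}: genome {row.genome_id}: unknown group {row.group!r}"
            )
        traits[row.genome_id] = row.group
    return traits


def assemble_genomes(
    genes: Sequence[GeneRecord],
    traits: Mapping[str, str] | None = None,
    genome_sizes: Mapping[str, float] | None = None,
) -> list[GenomeRecord]:
    """Partition genes into GenomeRecords (every gene lands in exactly one)."""
    by_genome: dict[str, list[GeneRecord]] = {}
    for g in genes:
        by_genome.setdefault(g.genome_id, []).append(g)
    genomes = []
    for genome_id in sorted(by_genome):
        genomes.append(
            GenomeRecord(
                genome_id=genome_id,
                group=(traits or {}).get(genome_id),
                genes=sorted(by_genome[genome_id], key=lambda g: g.gene_id),
                genome_size_mb=(genome_sizes or {}).get(genome_id),
            )
        )
    return genomes


# ---------------------------------------------------------------------------
# Matrices

def write_matrix(matrix: pd.DataFrame, path: str | Path, precision: int = 6) -> None:
    """Write a labeled square matrix as TSV (first column = row labels)."""
    if matrix.shape[0] == 0 or matrix.shape[1] == 0:
        raise ValueError("cannot write an empty matrix")
    if matrix.shape[0] != matrix.shape[1]:
        raise ValueError(f"matrix is not square: {matrix.shape}")
    matrix.to_csv(path, sep="\t", float_format=f"%.{precision}f",
                  index_label="label")


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a TSV matrix written by :func:`write_matrix`."""
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    df.index.name = None
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df
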