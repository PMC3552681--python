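"""K80 distances among aligned gene copies and the independent-entry bootstrap.

The Kimura two-parameter (K80) model distinguishes transitions (A<->G,
C<->T) from transversions.  With P and Q the observed proportions of
transition- and transversion-differing sites among comparable columns,
the distance is

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)   [substitutions/site]

Columns where either sequence carries a gap or an ambiguity code are
excluded pairwise before counting.

Mean distances are pooled within genomes (between paralogs, d_W) and
between genomes (between orthologs, d_B).  Their uncertainty is assessed
by a two-layer resampling: each replicate first draws a random maximal
set of matrix entries that share no row or column index (a maximal
matching on the copy labels, the proxy for statistically independent
observations), then bootstrap-resamples that set with replacement and
records its mean.  The 2.5/97.5 percentiles of the replicate means give
the 95% confidence interval.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")
_VALID = frozenset("ACGT")


class SaturationError(ValueError):
    """Observed divergence too high for a finite K80 distance."""


class NoComparableSitesError(ValueError):
    """No gap- and ambiguity-free columns shared by the pair."""


def comparable_sites(aligned_a: str, aligned_b: str) -> tuple[str, str]:
    """Drop columns where either sequence has a gap or ambiguity (pairwise deletion)."""
    if len(aligned_a) != len(aligned_b):
        raise ValueError(
            f"aligned lengths differ: {len(aligned_a)} vs {len(aligned_b)}")
    a_out, b_out = [], []
    for x, y in zip(aligned_a.upper(), aligned_b.upper()):
        if x in _VALID and y in _VALID:
            a_out.append(x)
            b_out.append(y)
    return "".join(a_out), "".join(b_out)


def substitution_proportions(aligned_a: str, aligned_b: str) -> tuple[float, float, int]:
    """Return (P, Q, n): transition and transversion proportions over comparable sites."""
    a, b = comparable_sites(aligned_a, aligned_b)
    n = len(a)
    if n == 0:
        raise NoComparableSitesError("no comparable sites after gap/ambiguity removal")
    ts = tv = 0
    for x, y in zip(a, b):
        if x == y:
            continue
        if (x in _PURINES) == (y in _PURINES):
            ts += 1
        else:
            tv += 1
    return ts / n, tv / n, n


def k80_distance(aligned_a: str, aligned_b: str) -> float:
    """K80 distance between two aligned nucleotide sequences.

    Raises :class:`SaturationError` when 1-2P-Q <= 0 or 1-2Q <= 0 and
    :class:`NoComparableSitesError` when no comparable columns remain.
    Identical sequences give exactly 0.
    """
    p, q, _ = substitution_proportions(aligned_a, aligned_b)
    if p == 0.0 and q == 0.0:
        return 0.0
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0.0 or w2 <= 0.0:
        raise SaturationError(
            f"saturated pair: P={p:.4f}, Q={q:.4f} (log argument <= 0)")
    return float(-0.5 * np.log(w1) - 0.25 * np.log(w2))


@dataclass
class LabeledDistanceMatrix:
    """Symmetric distance matrix whose labels map to genomes.

    ``saturated`` marks entries where the K80 transform diverged; those
    entries hold NaN and are excluded from means and resampling.
    """

    labels: tuple[str, ...]
    genome_of: dict[str, str]
    values: np.ndarray
    saturated: np.ndarray

    def __post_init__(self):
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        with np.errstate(invalid="ignore"):
            if not np.allclose(np.nan_to_num(self.values),
                               np.nan_to_num(self.values.T)):
                raise ValueError("matrix is not symmetric")
        missing = [l for l in self.labels if l not in self.genome_of]
        if missing:
            raise ValueError(f"labels without genome assignment: {missing[:5]}")

    @property
    def n(self) -> int:
        return len(self.labels)

    def pair_indices(self, scope: str) -> list[tuple[int, int]]:
        """Unordered index pairs in scope ('within' or 'between'), unsaturated only.

        Pairs come out in canonical (label-sorted) order, so resampling
        driven by a seeded RNG is invariant to the input label order.
        """
        if scope not in ("within", "between"):
            raise ValueError(f"scope must be 'within' or 'between', got {scope!r}")
        order = sorted(range(self.n), key=lambda i: self.labels[i])
        out = []
        for a, b in itertools.combinations(order, 2):
            i, j = min(a, b), max(a, b)
            if self.saturated[i, j]:
                continue
            same = (self.genome_of[self.labels[i]]
                    == self.genome_of[self.labels[j]])
            if (scope == "within") == same:
                out.append((i, j))
        return out

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.labels),
                            columns=list(self.labels))


def distance_matrix(
    aligned_copies: Sequence[tuple[str, str]],
    genome_of: Mapping[str, str],
) -> LabeledDistanceMatrix:
    """All-pairs K80 distances for labeled aligned copies.

    Saturated pairs are flagged (NaN) rather than raised, so one runaway
    pair does not abort a whole-matrix computation.
    """
    labels = tuple(label for label, _ in aligned_copies)
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate copy labels")
    seqs = [seq for _, seq in aligned_copies]
    lengths = {len(s) for s in seqs}
    if len(lengths) > 1:
        raise ValueError(f"aligned lengths differ: {sorted(lengths)}")
    n = len(labels)
    values = np.zeros((n, n))
    saturated = np.zeros((n, n), dtype=bool)
    for i, j in itertools.combinations(range(n), 2):
        try:
            d = k80_distance(seqs[i], seqs[j])
        except SaturationError:
            d = np.nan
            saturated[i, j] = saturated[j, i] = True
        values[i, j] = values[j, i] = d
    return LabeledDistanceMatrix(
        labels=labels, genome_of=dict(genome_of), values=values,
        saturated=saturated)


def mean_within_between(matrix: LabeledDistanceMatrix) -> tuple[float, float]:
    """Pooled mean distances (d_W, d_B); NaN where no qualifying pairs exist."""
    out = []
    for scope in ("within", "between"):
        pairs = matrix.pair_indices(scope)
        if not pairs:
            warnings.warn(f"no qualifying {scope}-genome pairs; mean undefined",
                          stacklevel=2)
            out.append(float("nan"))
        else:
            out.append(float(np.mean([matrix.values[i, j] for i, j in pairs])))
    return out[0], out[1]


def independent_sample(
    matrix: LabeledDistanceMatrix,
    scope: str,
    rng: np.random.Generator,
) -> np.ndarray:
    """Distances from a random maximal matching on the copy labels.

    Entries are added in random order under the constraint that no label
    (row or column index) is used twice; the result is maximal -- no
    further in-scope entry could be added.  Sample size is therefore at
    most floor(n_labels / 2).
    """
    pairs = matrix.pair_indices(scope)
    if not pairs:
        raise ValueError(f"no qualifying {scope}-genome entries to sample")
    return _matching_sample(pairs, matrix.values, rng)


def _matching_sample(pairs: Sequence[tuple[int, int]], values: np.ndarray,
                     rng: np.random.Generator) -> np.ndarray:
    order = rng.permutation(len(pairs))
    used: set[int] = set()
    out = []
    for k in order:
        i, j = pairs[k]
        if i in used or j in used:
            continue
        used.update((i, j))
        out.append(values[i, j])
    return np.asarray(out)


@dataclass(frozen=True)
class BootstrapSummary:
    """Resampled mean distance with a 95% percentile confidence interval."""

    scope: str
    observed_mean: float
    boot_mean: float
    ci_lower: float
    ci_upper: float
    n_rep: int
    seed: int | None

    def __post_init__(self):
        if self.n_rep > 0 and not (
            self.ci_lower <= self.boot_mean + 1e-12
            and self.boot_mean <= self.ci_upper + 1e-12
        ):
            raise ValueError("CI bounds do not bracket the bootstrap mean")


def bootstrap_summary(
    matrix: LabeledDistanceMatrix,
    scope: str,
    n_rep: int = 10_000,
    seed: int | None = 42,
    resample: bool = True,
) -> BootstrapSummary:
    """Two-layer resampling of mean distance in the given scope.

    Each replicate draws a random maximal independent matching, bootstrap
    resamples it with replacement to its own size (disable the second
    layer with ``resample=False``), and records its mean.  ``n_rep = 0``
    returns the observed mean only (NaN interval).
    """
    pairs = matrix.pair_indices(scope)
    if not pairs:
        raise ValueError(f"no qualifying {scope}-genome entries")
    observed = float(np.mean([matrix.values[i, j] for i, j in pairs]))
    if n_rep == 0:
        return BootstrapSummary(scope=scope, observed_mean=observed,
                                boot_mean=float("nan"),
                                ci_lower=float("nan"), ci_upper=float("nan"),
                                n_rep=0, seed=seed)
    rng = np.random.default_rng(seed)
    means = np.empty(n_rep)
    for r in range(n_rep):
        sample = _matching_sample(pairs, matrix.values, rng)
        if resample:
            sample = rng.choice(sample, size=sample.size, replace=True)
        means[r] = sample.mean()
    lo, hi = np.percentile(means, [2.5, 97.5])
    return BootstrapSummary(scope=scope, observed_mean=observed,
                            boot_mean=float(means.mean()),
                            ci_lower=float(lo), ci_upper=float(hi),
                            n_rep=n_rep, seed=seed)


def count_snps(copy_a: str, copy_b: str) -> int:
    """Number of gap-free columns at which two aligned copies differ."""
    if len(copy_a) != len(copy_b):
        raise ValueError(
            f"aligned lengths differ: {len(copy_a)} vs {len(copy_b)}")
    a, b = comparable_sites(copy_a, copy_b)
    return sum(1 for x, y in zip(a, b) if x != y)


def summarize_within_between(
    matrix: LabeledDistanceMatrix,
    n_rep: int = 10_000,
    seed: int | None = 42,
) -> pd.DataFrame:
    """Table of d_W/d_B with bootstrap means and 95% CIs (one row per scope)."""
    rows = []
    for scope in ("within", "between"):
        if not matrix.pair_indices(scope):
            continue
        s = bootstrap_summary(matrix, scope, n_rep=n_rep, seed=seed)
        rows.append({
            "scope": scope,
            "observed_mean": s.observed_mean,
            "boot_mean": s.boot_mean,
            "ci_lower": s.ci_lower,
            "ci_upper": s.ci_upper,
            "n_rep": s.n_rep,
        })
    return pd.DataFrame(rows)
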