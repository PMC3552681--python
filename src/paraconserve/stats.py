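"""Copy-number vs differentiation-group correlation and the significance screen.

Genomes carry an ordinal differentiation group: G0 (no differentiation),
G1 (circadian control only), G2 (reversible differentiated cells), G3
(terminal differentiation).  Groups are encoded 0..3 -- an equally spaced
ordinal convention -- and each gene family's copy-number vector is tested
against that encoding with both Spearman's rank correlation (rho) and
Pearson's product-moment correlation (R).  A family is flagged
significant when either test's two-sided p-value falls below alpha
(default 0.01); per-test flags are also reported.  No multiple-testing
correction is applied by default, with an optional Benjamini-Hochberg
adjustment for users who prefer controlled false-discovery rates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .seqio import GROUP_LABELS, GenomeRecord

_GROUP_CODE = {label: code for code, label in enumerate(GROUP_LABELS)}


def encode_groups(genomes: Sequence[GenomeRecord | str]) -> np.ndarray:
    """Encode G0..G3 labels as ordinals 0..3; unlabeled genomes are an error."""
    codes = []
    for g in genomes:
        label = g if isinstance(g, str) else g.group
        ident = g if isinstance(g, str) else g.genome_id
        if label not in _GROUP_CODE:
            raise ValueError(f"genome {ident!r}: missing or unknown group {label!r}")
        codes.append(_GROUP_CODE[label])
    return np.asarray(codes, dtype=int)


def pearson_r(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson product-moment correlation with two-sided t-test p (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("length mismatch")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        raise ValueError("zero variance: correlation undefined")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def spearman_rho(
    x: Sequence[float],
    y: Sequence[float],
    exact: bool = False,
) -> tuple[float, float]:
    """Spearman rank correlation (average ranks for ties), two-sided p.

    The default p-value uses the t approximation; ``exact=True`` switches
    to a full permutation p-value, feasible for n <= 10.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("length mismatch")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    if np.std(rx) == 0.0 or np.std(ry) == 0.0:
        raise ValueError("zero rank variance: correlation undefined")
    rho, p = sps.spearmanr(x, y)
    if exact:
        if x.size > 10:
            raise ValueError("exact permutation p-value limited to n <= 10")
        res = sps.permutation_test(
            (x,), lambda xs: sps.spearmanr(xs, y).statistic,
            permutation_type="pairings", alternative="two-sided",
            n_resamples=np.inf)
        p = float(res.pvalue)
    return float(rho), float(p)


@dataclass(frozen=True)
class CorrelationResult:
    """Per-family correlation of copy number with differentiation group."""

    gene_family: str
    spearman_rho: float
    pearson_r: float
    p_spearman: float
    p_pearson: float
    n: int
    significant: bool
    significant_spearman: bool
    significant_pearson: bool
    p_adjusted_spearman: float | None = None
    p_adjusted_pearson: float | None = None


def _bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    m = pvals.size
    order = np.argsort(pvals)
    adj = np.empty(m)
    running = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        rank = m - rank_from_end
        running = min(running, pvals[idx] * m / rank)
        adj[idx] = running
    return adj


def correlation_screen(
    copy_numbers: pd.DataFrame,
    groups: Mapping[str, str] | Sequence[int] | np.ndarray,
    alpha: float = 0.01,
    adjust: bool = False,
) -> list[CorrelationResult]:
    """Test every gene family's copy numbers against the group ordinals.

    ``copy_numbers`` has one row per family, one column per genome.
    ``groups`` is either a genome_id -> G-label mapping or a pre-encoded
    ordinal vector aligned to the matrix columns.  Constant-copy families
    have undefined correlation and are excluded with a warning.  Results
    are sorted by Spearman rho, descending.  When ``adjust`` is true the
    significance flags use Benjamini-Hochberg adjusted p-values instead.
    """
    if isinstance(groups, Mapping):
        missing = [c for c in copy_numbers.columns if c not in groups]
        if missing:
            raise ValueError(f"genomes without group labels: {missing[:5]}")
        codes = encode_groups([groups[c] for c in copy_numbers.columns])
    else:
        codes = np.asarray(groups, dtype=int)
        if codes.size != copy_numbers.shape[1]:
            raise ValueError("group vector length does not match matrix columns")

    families, rhos, rs, ps_s, ps_p = [], [], [], [], []
    for family, row in copy_numbers.iterrows():
        y = row.to_numpy(dtype=float)
        if np.std(y) == 0.0:
            warnings.warn(
                f"family {family}: constant copy number, correlation undefined; "
                "excluded", stacklevel=2)
            continue
        rho, p_s = spearman_rho(codes, y)
        r, p_p = pearson_r(codes, y)
        families.append(str(family))
        rhos.append(rho)
        rs.append(r)
        ps_s.append(p_s)
        ps_p.append(p_p)

    adj_s = _bh_adjust(np.asarray(ps_s)) if (adjust and families) else None
    adj_p = _bh_adjust(np.asarray(ps_p)) if (adjust and families) else None

    results = []
    for k, family in enumerate(families):
        eff_s = adj_s[k] if adjust else ps_s[k]
        eff_p = adj_p[k] if adjust else ps_p[k]
        sig_s = bool(eff_s < alpha)
        sig_p = bool(eff_p < alpha)
        results.append(CorrelationResult(
            gene_family=family,
            spearman_rho=rhos[k], pearson_r=rs[k],
            p_spearman=ps_s[k], p_pearson=ps_p[k],
            n=int(copy_numbers.shape[1]),
            significant=sig_s or sig_p,
            significant_spearman=sig_s,
            significant_pearson=sig_p,
            p_adjusted_spearman=float(adj_s[k]) if adjust else None,
            p_adjusted_pearson=float(adj_p[k]) if adjust else None,
        ))
    results.sort(key=lambda r: (-r.spearman_rho, r.gene_family))
    return results


def results_to_frame(results: Sequence[CorrelationResult]) -> pd.DataFrame:
    """Flatten screen results for TSV export."""
    return pd.DataFrame([{
        "gene_family": r.gene_family,
        "spearman_rho": r.spearman_rho,
        "pearson_r": r.pearson_r,
        "p_spearman": r.p_spearman,
        "p_pearson": r.p_pearson,
        "n": r.n,
        "significant": r.significant,
        "significant_spearman": r.significant_spearman,
        "significant_pearson": r.significant_pearson,
    } for r in results])
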