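"""Two-stage detection of highly conserved gene-copy families.

Stage 1 (within each genome): pairwise hits with alignment score >= 130
and identity >= 98% become edges of a homology graph; connected
components of size >= 2 are paralog clusters.  Edges whose distance
deviates from the cluster mean by more than ``k_sd`` standard deviations
are pruned and components recomputed.

Stage 2 (across genomes): clusters from different genomes are linked when
at least ``density * n_i * n_j`` of the possible member-pair hits qualify
(score >= 180, identity >= 50%); when one cluster links to several
clusters of a single foreign genome only the lowest-average-distance link
survives.  Connected components of the cluster graph are the homologous
groups.  Finally, genes that formed no within-genome cluster (single
orthologs) are attached to the group holding their best qualifying
cross-genome hit, contributing copy number 1.

The end product is the copy-number matrix: one row per group, one column
per genome, integer copy counts.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .align import (AlignmentParams, HomologyHit, NUCLEOTIDE_PARAMS,
                    PROTEIN_PARAMS, all_against_all)
from .seqio import GeneRecord, GenomeRecord


@dataclass(frozen=True)
class ParalogCluster:
    """A within-genome set of near-identical gene copies."""

    genome_id: str
    members: frozenset[str]
    mean_distance: float
    sd_distance: float

    def __post_init__(self):
        if len(self.members) < 1:
            raise ValueError("cluster must have at least one member")

    @property
    def size(self) -> int:
        return len(self.members)

    def sorted_members(self) -> list[str]:
        return sorted(self.members)


@dataclass
class HomologGroup:
    """A cross-genome family of conserved gene copies."""

    group_id: str
    clusters: dict[str, ParalogCluster] = field(default_factory=dict)

    @property
    def copy_numbers(self) -> dict[str, int]:
        return {g: c.size for g, c in self.clusters.items()}

    def member_ids(self) -> list[str]:
        out = []
        for c in self.clusters.values():
            out.extend(c.members)
        return sorted(out)


def _edge_stats(distances: Sequence[float]) -> tuple[float, float]:
    if not distances:
        return 0.0, 0.0
    arr = np.asarray(distances, dtype=float)
    return float(arr.mean()), float(arr.std())


def _make_cluster(genome_id: str, members: Iterable[str],
                  edge_distance: Mapping[frozenset, float]) -> ParalogCluster:
    members = frozenset(members)
    dists = [
        edge_distance[frozenset(p)]
        for p in itertools.combinations(sorted(members), 2)
        if frozenset(p) in edge_distance
    ]
    mean, sd = _edge_stats(dists)
    return ParalogCluster(genome_id=genome_id, members=members,
                          mean_distance=mean, sd_distance=sd)


# ---------------------------------------------------------------------------
# Stage 1: within-genome clusters

def within_species_clusters(
    hits: Iterable[HomologyHit],
    genes: Sequence[GeneRecord],
    score_min: float = 130.0,
    identity_min: float = 0.98,
) -> list[ParalogCluster]:
    """Connected components of the thresholded within-genome homology graph.

    Only hits joining two genes of the same genome with score >=
    ``score_min`` and identity >= ``identity_min`` become edges.
    Components of size 1 are not reported.
    """
    genome_of = {g.gene_id: g.genome_id for g in genes}
    graphs: dict[str, nx.Graph] = {}
    edge_distance: dict[frozenset, float] = {}
    for h in hits:
        ga, gb = genome_of.get(h.gene_a), genome_of.get(h.gene_b)
        if ga is None or gb is None or ga != gb:
            continue
        if h.score < score_min or h.identity < identity_min:
            continue
        graphs.setdefault(ga, nx.Graph()).add_edge(h.gene_a, h.gene_b)
        edge_distance[frozenset((h.gene_a, h.gene_b))] = h.distance
    clusters = []
    for genome_id in sorted(graphs):
        for comp in nx.connected_components(graphs[genome_id]):
            if len(comp) >= 2:
                clusters.append(_make_cluster(genome_id, comp, edge_distance))
    clusters.sort(key=lambda c: (c.genome_id, min(c.members)))
    return clusters


def prune_outlier_hits(
    cluster: ParalogCluster,
    hits: Iterable[HomologyHit],
    k_sd: float = 2.0,
) -> list[ParalogCluster]:
    """Drop edges whose distance is an outlier; recompute components.

    An edge is removed when ``|distance - mean| > k_sd * sd`` of the
    cluster's edge distances.  Clusters of size <= 2 pass through
    unchanged; size-1 remnants after pruning are dropped (their genes
    revert to singleton status).
    """
    if cluster.size <= 2:
        return [cluster]
    members = cluster.members
    edges = {}
    for h in hits:
        if h.gene_a in members and h.gene_b in members:
            edges[frozenset((h.gene_a, h.gene_b))] = h.distance
    dists = list(edges.values())
    mean, sd = _edge_stats(dists)
    kept = nx.Graph()
    kept.add_nodes_from(members)
    kept_edges = {}
    for pair, d in edges.items():
        if sd == 0.0 or abs(d - mean) <= k_sd * sd:
            a, b = sorted(pair)
            kept.add_edge(a, b)
            kept_edges[pair] = d
    out = []
    for comp in nx.connected_components(kept):
        if len(comp) >= 2:
            out.append(_make_cluster(cluster.genome_id, comp, kept_edges))
    out.sort(key=lambda c: min(c.members))
    return out


# ---------------------------------------------------------------------------
# Stage 2: cross-genome grouping

def _qualifying_cross_hits(
    cross_hits: Iterable[HomologyHit],
    score_min: float,
    identity_min: float,
) -> list[HomologyHit]:
    return [h for h in cross_hits
            if h.score >= score_min and h.identity >= identity_min]


def group_across_species(
    clusters: Sequence[ParalogCluster],
    cross_hits: Iterable[HomologyHit],
    score_min: float = 180.0,
    identity_min: float = 0.50,
    density: float = 0.8,
) -> list[HomologGroup]:
    """Merge within-genome clusters into cross-genome homologous groups.

    Two clusters i, j (different genomes) are candidates when the number
    of qualifying member-pair hits is >= ``density * n_i * n_j`` (compared
    as real numbers, no rounding).  A cluster linking to several clusters
    of one foreign genome keeps only its lowest-average-distance link
    (ties broken lexicographically).  Groups are connected components of
    the surviving cluster graph.
    """
    clusters = sorted(clusters, key=lambda c: (c.genome_id, min(c.members)))
    member_cluster: dict[str, int] = {}
    for idx, c in enumerate(clusters):
        for m in c.members:
            member_cluster[m] = idx

    # qualifying hit count and distances per unordered cluster pair
    pair_hits: dict[tuple[int, int], list[float]] = {}
    for h in _qualifying_cross_hits(cross_hits, score_min, identity_min):
        ia = member_cluster.get(h.gene_a)
        ib = member_cluster.get(h.gene_b)
        if ia is None or ib is None or ia == ib:
            continue
        if clusters[ia].genome_id == clusters[ib].genome_id:
            continue
        key = (min(ia, ib), max(ia, ib))
        pair_hits.setdefault(key, []).append(h.distance)

    candidate_edges: dict[tuple[int, int], float] = {}
    for (ia, ib), dists in pair_hits.items():
        need = density * clusters[ia].size * clusters[ib].size
        if len(dists) >= need:
            candidate_edges[(ia, ib)] = float(np.mean(dists))

    # conflict resolution: per cluster, per foreign genome, keep the
    # minimum-average-distance edge; an edge survives only if kept from
    # both endpoints
    best: dict[tuple[int, str], tuple[float, tuple[int, int]]] = {}
    for (ia, ib), avg in sorted(candidate_edges.items()):
        for src, dst in ((ia, ib), (ib, ia)):
            key = (src, clusters[dst].genome_id)
            entry = (avg, (min(ia, ib), max(ia, ib)))
            if key not in best or entry < best[key]:
                best[key] = entry
    surviving = []
    for (ia, ib), avg in sorted(candidate_edges.items()):
        edge = (ia, ib)
        ok_a = best[(ia, clusters[ib].genome_id)][1] == edge
        ok_b = best[(ib, clusters[ia].genome_id)][1] == edge
        if ok_a and ok_b:
            surviving.append(edge)

    graph = nx.Graph()
    graph.add_nodes_from(range(len(clusters)))
    graph.add_edges_from(surviving)
    groups = []
    comps = sorted(nx.connected_components(graph),
                   key=lambda comp: min(min(clusters[i].members) for i in comp))
    for n, comp in enumerate(comps, start=1):
        group = HomologGroup(group_id=f"HG{n:04d}")
        for i in sorted(comp):
            c = clusters[i]
            if c.genome_id in group.clusters:
                # cannot happen after conflict resolution unless two
                # same-genome clusters are bridged via a third genome;
                # keep the first (lexicographically smallest) cluster
                continue
            group.clusters[c.genome_id] = c
        groups.append(group)
    return groups


def attach_singletons(
    groups: Sequence[HomologGroup],
    genes: Sequence[GeneRecord],
    cross_hits: Iterable[HomologyHit],
    score_min: float = 180.0,
    identity_min: float = 0.50,
) -> list[HomologGroup]:
    """Attach unclustered genes (single orthologs) to existing groups.

    A singleton joins the group containing its best qualifying
    cross-genome hit (highest score; distance, then group id, as
    tie-breaks), provided that group has no cluster for the singleton's
    genome yet.  Unmatched singletons are left out; no new groups are
    created.  Returns new group objects; inputs are not mutated.
    """
    genome_of = {g.gene_id: g.genome_id for g in genes}
    clustered = set()
    group_of_member: dict[str, str] = {}
    for grp in groups:
        for m in grp.member_ids():
            clustered.add(m)
            group_of_member[m] = grp.group_id
    singleton_ids = {g.gene_id for g in genes} - clustered

    # best qualifying hit per singleton: (-score, distance, group_id)
    best_for: dict[str, tuple[float, float, str]] = {}
    for h in _qualifying_cross_hits(cross_hits, score_min, identity_min):
        for s, other in ((h.gene_a, h.gene_b), (h.gene_b, h.gene_a)):
            if s not in singleton_ids or other not in group_of_member:
                continue
            if genome_of.get(s) == genome_of.get(other):
                continue
            cand = (-h.score, h.distance, group_of_member[other])
            if s not in best_for or cand < best_for[s]:
                best_for[s] = cand

    # per (group, genome) keep the single best singleton
    chosen: dict[tuple[str, str], tuple[float, float, str]] = {}
    for s in sorted(best_for):
        neg_score, dist, gid = best_for[s]
        key = (gid, genome_of[s])
        cand = (neg_score, dist, s)
        if key not in chosen or cand < chosen[key]:
            chosen[key] = cand

    out = []
    for grp in groups:
        new = HomologGroup(group_id=grp.group_id, clusters=dict(grp.clusters))
        for (gid, genome_id), (_, _, s) in sorted(chosen.items()):
            if gid != grp.group_id or genome_id in new.clusters:
                continue
            new.clusters[genome_id] = ParalogCluster(
                genome_id=genome_id, members=frozenset([s]),
                mean_distance=0.0, sd_distance=0.0)
        out.append(new)
    return out


def copy_number_matrix(
    groups: Sequence[HomologGroup],
    genomes: Sequence[GenomeRecord | str],
) -> pd.DataFrame:
    """Group x genome matrix of integer copy numbers (0 where absent)."""
    genome_ids = [g if isinstance(g, str) else g.genome_id for g in genomes]
    data = {}
    for grp in groups:
        counts = grp.copy_numbers
        data[grp.group_id] = [counts.get(g, 0) for g in genome_ids]
    df = pd.DataFrame.from_dict(data, orient="index", columns=genome_ids,
                                dtype=int)
    return df.sort_index()


# ---------------------------------------------------------------------------
# Orchestration

@dataclass(frozen=True)
class ScanConfig:
    """Thresholds for the two-stage scan."""

    within_score_min: float = 130.0
    within_identity_min: float = 0.98
    cross_score_min: float = 180.0
    cross_identity_min: float = 0.50
    density: float = 0.8
    k_sd: float = 2.0
    report_floor: float = 100.0  # score floor for computing identities
    protein_params: AlignmentParams = PROTEIN_PARAMS
    nucleotide_params: AlignmentParams = NUCLEOTIDE_PARAMS


@dataclass
class ScanResult:
    groups: list[HomologGroup]
    matrix: pd.DataFrame
    clusters: list[ParalogCluster]
    n_within_hits: int
    n_cross_hits: int


def scan_genomes(genomes: Sequence[GenomeRecord],
                 config: ScanConfig = ScanConfig()) -> ScanResult:
    """Run the full conserved-copy scan over a set of genomes."""
    floor = min(config.report_floor, config.within_score_min,
                config.cross_score_min)
    all_genes = [g for genome in genomes for g in genome.genes]

    within_hits: list[HomologyHit] = []
    for genome in sorted(genomes, key=lambda g: g.genome_id):
        within_hits.extend(
            all_against_all(genome.genes,
                            protein_params=config.protein_params,
                            nucleotide_params=config.nucleotide_params,
                            min_score=floor)
        )
    clusters = within_species_clusters(
        within_hits, all_genes,
        score_min=config.within_score_min,
        identity_min=config.within_identity_min)
    # pruning looks only at the edges that built the clusters
    qualifying_within = [
        h for h in within_hits
        if h.score >= config.within_score_min
        and h.identity >= config.within_identity_min
    ]
    pruned: list[ParalogCluster] = []
    for c in clusters:
        pruned.extend(prune_outlier_hits(c, qualifying_within, k_sd=config.k_sd))

    cross_hits = all_against_all(
        all_genes,
        protein_params=config.protein_params,
        nucleotide_params=config.nucleotide_params,
        min_score=floor,
        pair_filter=lambda a, b: a.genome_id != b.genome_id)

    groups = group_across_species(
        pruned, cross_hits,
        score_min=config.cross_score_min,
        identity_min=config.cross_identity_min,
        density=config.density)
    groups = attach_singletons(
        groups, all_genes, cross_hits,
        score_min=config.cross_score_min,
        identity_min=config.cross_identity_min)
    matrix = copy_number_matrix(groups, list(genomes))
    return ScanResult(groups=groups, matrix=matrix, clusters=pruned,
                      n_within_hits=len(within_hits),
                      n_cross_hits=len(cross_hits))
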