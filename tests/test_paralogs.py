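import itertools

import numpy as np
import pandas as pd
import pytest

from paraconserve.align import HomologyHit
from paraconserve.paralogs import (HomologGroup, ParalogCluster, ScanConfig,
                                   attach_singletons, copy_number_matrix,
                                   group_across_species, prune_outlier_hits,
                                   scan_genomes, within_species_clusters)
from paraconserve.seqio import GeneType, GenomeRecord
from paraconserve.synthetic import SimulationConfig, generate_dataset
from conftest import make_gene
from _oracles import reachability_components

PROT = "MKVLWAALLVTFLAGCQAKVEQAVETEPEPELRQQTEWQSGQRWELALGRFWDYLRWVQT"


def hit(a, b, score=200.0, identity=1.0):
    return HomologyHit(gene_a=a, gene_b=b, score=score, identity=identity)


def genes_in(genome_id, n, prefix="g"):
    return [make_gene(f"{prefix}{i}", genome_id, PROT) for i in range(n)]


# ---------------------------------------------------------------------------
# stage 1

def test_three_identical_genes_form_one_cluster():
    genes = genes_in("x", 3)
    hits = [hit(a.gene_id, b.gene_id)
            for a, b in itertools.combinations(genes, 2)]
    clusters = within_species_clusters(hits, genes)
    assert len(clusters) == 1
    assert clusters[0].members == {"g0", "g1", "g2"}
    assert clusters[0].mean_distance == 0.0


def test_identity_below_threshold_gives_no_cluster():
    genes = genes_in("x", 2)
    clusters = within_species_clusters([hit("g0", "g1", identity=0.97)], genes)
    assert clusters == []


def test_score_below_threshold_gives_no_cluster():
    genes = genes_in("x", 2)
    clusters = within_species_clusters([hit("g0", "g1", score=129.0)], genes)
    assert clusters == []


def test_cross_genome_hits_ignored_within_stage():
    genes = genes_in("x", 1) + [make_gene("h0", "y", PROT)]
    assert within_species_clusters([hit("g0", "h0")], genes) == []


@pytest.mark.parametrize("seed", range(5))
def test_components_match_reachability_oracle(seed):
    """Cluster membership equals brute-force transitive closure."""
    rng = np.random.default_rng(seed)
    genes = genes_in("x", 12)
    ids = [g.gene_id for g in genes]
    hits = []
    edges = []
    for a, b in itertools.combinations(ids, 2):
        if rng.random() < 0.15:
            hits.append(hit(a, b))
            edges.append((a, b))
    clusters = within_species_clusters(hits, genes)
    oracle = {c for c in reachability_components(ids, edges) if len(c) >= 2}
    assert {frozenset(c.members) for c in clusters} == oracle


def test_identity_threshold_monotonicity():
    """Raising identity_min never increases any cluster's size."""
    rng = np.random.default_rng(3)
    genes = genes_in("x", 10)
    hits = [hit(a.gene_id, b.gene_id, identity=float(rng.uniform(0.9, 1.0)))
            for a, b in itertools.combinations(genes, 2)
            if rng.random() < 0.4]
    sizes = []
    for thr in (0.90, 0.95, 0.98, 0.99):
        clusters = within_species_clusters(hits, genes, identity_min=thr)
        sizes.append(sorted((len(c.members) for c in clusters), reverse=True))
    for lo, hi in zip(sizes[1:], sizes[:-1]):
        # every cluster at the stricter threshold fits inside one at the looser
        assert sum(lo) <= sum(hi)
        assert len(lo) == 0 or (len(hi) > 0 and max(lo) <= max(hi))


# ---------------------------------------------------------------------------
# pruning

def _cluster_with_edges(dists):
    """4-member cluster; dists maps (i,j) -> distance for members m0..m3."""
    members = [f"m{i}" for i in range(4)]
    hits = [hit(f"m{i}", f"m{j}", identity=1.0 - d)
            for (i, j), d in dists.items()]
    genes = [make_gene(m, "x", PROT) for m in members]
    clusters = within_species_clusters(hits, genes, identity_min=0.0)
    assert len(clusters) == 1
    return clusters[0], hits


def test_prune_keeps_equal_distances():
    dists = {(i, j): 0.01 for i, j in itertools.combinations(range(4), 2)}
    cluster, hits = _cluster_with_edges(dists)
    out = prune_outlier_hits(cluster, hits)
    assert len(out) == 1 and out[0].members == cluster.members


def test_prune_removes_outlier_edge_and_recomputes():
    # five edges at 0, one far-off edge at 0.5: |0.5-mean| > 2 sd, edge dropped;
    # the component survives through the remaining edges
    dists = {(i, j): 0.0 for i, j in itertools.combinations(range(4), 2)}
    dists[(2, 3)] = 0.5
    cluster, hits = _cluster_with_edges(dists)
    out = prune_outlier_hits(cluster, hits)
    assert len(out) == 1
    assert out[0].members == {"m0", "m1", "m2", "m3"}
    assert max(out[0].mean_distance, 0.0) == 0.0  # outlier edge gone from stats


def test_prune_splits_component_when_bridge_is_outlier():
    # two tight pairs joined by one long bridge edge
    dists = {(0, 1): 0.0, (2, 3): 0.0, (1, 2): 0.5}
    cluster, hits = _cluster_with_edges(dists)
    out = prune_outlier_hits(cluster, hits, k_sd=1.0)
    assert {frozenset(c.members) for c in out} == {
        frozenset({"m0", "m1"}), frozenset({"m2", "m3"})}


def test_prune_passes_pairs_through():
    pair = ParalogCluster(genome_id="x", members=frozenset({"a", "b"}),
                          mean_distance=0.0, sd_distance=0.0)
    assert prune_outlier_hits(pair, [hit("a", "b")]) == [pair]


# ---------------------------------------------------------------------------
# stage 2

def _two_clusters(n_hits, identity=0.8, score=200.0):
    c1 = ParalogCluster("x", frozenset({"x0", "x1"}), 0.0, 0.0)
    c2 = ParalogCluster("y", frozenset({"y0", "y1"}), 0.0, 0.0)
    pairs = list(itertools.product(sorted(c1.members), sorted(c2.members)))
    hits = [hit(a, b, score=score, identity=identity)
            for a, b in pairs[:n_hits]]
    return [c1, c2], hits


def test_density_rule_full_bipartite_merges():
    clusters, hits = _two_clusters(4)  # 4 >= 0.8*2*2 = 3.2
    groups = group_across_species(clusters, hits)
    assert len(groups) == 1
    assert groups[0].copy_numbers == {"x": 2, "y": 2}


def test_density_rule_three_of_four_hits_does_not_merge():
    clusters, hits = _two_clusters(3)  # 3 < 3.2: real-valued comparison
    groups = group_across_species(clusters, hits)
    assert len(groups) == 2


def test_conflict_resolved_by_lowest_average_distance():
    ca = ParalogCluster("x", frozenset({"x0", "x1"}), 0.0, 0.0)
    cb = ParalogCluster("y", frozenset({"y0", "y1"}), 0.0, 0.0)
    cc = ParalogCluster("y", frozenset({"z0", "z1"}), 0.0, 0.0)
    hits = []
    for m in ("x0", "x1"):
        for o in ("y0", "y1"):
            hits.append(hit(m, o, identity=0.9))   # avg distance 0.1
        for o in ("z0", "z1"):
            hits.append(hit(m, o, identity=0.7))   # avg distance 0.3
    groups = group_across_species([ca, cb, cc], hits)
    by_members = {frozenset(g.member_ids()) for g in groups}
    assert frozenset({"x0", "x1", "y0", "y1"}) in by_members
    assert frozenset({"z0", "z1"}) in by_members


def test_group_across_species_idempotent():
    clusters, hits = _two_clusters(4)
    first = group_across_species(clusters, hits)
    again = group_across_species(
        [c for g in first for c in g.clusters.values()], hits)
    assert {frozenset(g.member_ids()) for g in again} == \
        {frozenset(g.member_ids()) for g in first}


# ---------------------------------------------------------------------------
# singleton attachment

def _one_group():
    c1 = ParalogCluster("x", frozenset({"x0", "x1"}), 0.0, 0.0)
    return [HomologGroup(group_id="HG0001", clusters={"x": c1})]


def _singleton_genes():
    return [make_gene("x0", "x", PROT), make_gene("x1", "x", PROT),
            make_gene("s0", "z", PROT)]


def test_singleton_attaches_with_copy_number_one():
    groups = attach_singletons(_one_group(), _singleton_genes(),
                               [hit("s0", "x0", identity=0.99)])
    assert groups[0].copy_numbers == {"x": 2, "z": 1}


def test_singleton_below_identity_not_attached():
    groups = attach_singletons(_one_group(), _singleton_genes(),
                               [hit("s0", "x0", identity=0.4)])
    assert groups[0].copy_numbers == {"x": 2}


def test_singleton_joins_higher_score_group():
    c1 = ParalogCluster("x", frozenset({"x0", "x1"}), 0.0, 0.0)
    c2 = ParalogCluster("y", frozenset({"y0", "y1"}), 0.0, 0.0)
    groups = [HomologGroup("HG0001", {"x": c1}), HomologGroup("HG0002", {"y": c2})]
    genes = [make_gene(m, g, PROT) for m, g in
             [("x0", "x"), ("x1", "x"), ("y0", "y"), ("y1", "y"), ("s0", "z")]]
    hits = [hit("s0", "x0", score=300.0, identity=0.8),
            hit("s0", "y0", score=250.0, identity=0.8)]
    out = attach_singletons(groups, genes, hits)
    assert out[0].copy_numbers == {"x": 2, "z": 1}
    assert out[1].copy_numbers == {"y": 2}


def test_singleton_never_creates_new_group():
    out = attach_singletons([], _singleton_genes(),
                            [hit("s0", "x0", identity=0.99)])
    assert out == []


# ---------------------------------------------------------------------------
# copy-number matrix and end-to-end

def test_copy_number_matrix_planted_counts():
    sizes = {"a": 2, "b": 2, "c": 4}
    clusters = {g: ParalogCluster(g, frozenset(f"{g}{i}" for i in range(n)),
                                  0.0, 0.0) for g, n in sizes.items()}
    grp = HomologGroup("HG0001", clusters)
    m = copy_number_matrix([grp], ["a", "b", "c", "d"])
    assert list(m.loc["HG0001"]) == [2, 2, 4, 0]


def test_scan_recovers_planted_matrix(small_dataset):
    """End-to-end: planted copy numbers are recovered exactly."""
    result = scan_genomes(small_dataset.genomes)
    truth = small_dataset.truth.copy_matrix
    recovered = result.matrix.reindex(columns=truth.columns)
    assert sorted(map(tuple, recovered.values.tolist())) == \
        sorted(map(tuple, truth.values.tolist()))
    # group members agree with the planted family labels
    for grp in result.groups:
        families = {m.split("|")[1].rsplit("_", 1)[0] for m in grp.member_ids()}
        assert len(families) == 1


def test_gene_order_permutation_invariance(small_dataset):
    """Shuffling input gene order leaves the copy-number matrix identical."""
    result = scan_genomes(small_dataset.genomes)
    rng = np.random.default_rng(0)
    shuffled = []
    for genome in small_dataset.genomes:
        genes = list(genome.genes)
        rng.shuffle(genes)
        shuffled.append(GenomeRecord(genome_id=genome.genome_id,
                                     group=genome.group, genes=genes))
    result2 = scan_genomes(shuffled)
    pd.testing.assert_frame_equal(result.matrix, result2.matrix)
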