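"""Edge rule, clusters, dominance, classification, SHM branching metrics.

The edge set and the cluster partition are each checked against independent
brute-force oracles (O(n^2) predicate evaluation; transitive closure by
union-find) on randomized clone tables.
"""

import itertools
import math
import random

import pytest

from bcrnet.assembly import Clone, clones_from_records
from bcrnet.io import ClonotypeRecord, UsageError
from bcrnet.network import (
    LABEL_BI,
    LABEL_MONO,
    LABEL_NONE,
    LABEL_OLIGO,
    build_network,
    cdr3_distance,
    classify_sample,
    clone_key,
    display_size,
    edge_predicate,
    filter_singleton_clusters,
    find_clusters,
    score_dominance,
    shm_branching_metrics,
)


def _clone(v, j, cdr3, count, chain="IGH", total=None):
    rec = ClonotypeRecord(
        "s", chain, frozenset(v.split(",")), frozenset(j.split(",")), cdr3, count
    )
    return Clone(rec, count / total if total else 0.0, True)


def _clone_table(clones):
    """Recompute fractions over a list of (v, j, cdr3, count) tuples."""
    total = sum(c[3] for c in clones)
    return [_clone(v, j, cdr3, count, total=total) for v, j, cdr3, count in clones]


def random_clone_table(rnd, n_clones):
    """Random table with deliberate 1-bp families and shared/disjoint genes."""
    clones = {}
    while len(clones) < n_clones:
        v = "IGHV%d" % rnd.randint(1, 4)
        j = "IGHJ%d" % rnd.randint(1, 3)
        if rnd.random() < 0.3:
            v += ",IGHV%d" % rnd.randint(1, 4)
        length = rnd.choice([6, 9, 9, 9, 12])
        cdr3 = "".join(rnd.choice("ACGT") for _ in range(length))
        if clones and rnd.random() < 0.5:
            # mutate an existing CDR3 by one base to create linkable pairs
            base = rnd.choice(list(clones))[2]
            pos = rnd.randrange(len(base))
            cdr3 = base[:pos] + rnd.choice("ACGT") + base[pos + 1 :]
        key = (frozenset(v.split(",")), frozenset(j.split(",")), cdr3)
        if key not in clones:
            clones[key] = (v, j, cdr3, rnd.randint(1, 50))
    return _clone_table(list(clones.values()))


def brute_force_edges(clones, max_distance=1):
    edges = set()
    for a, b in itertools.combinations(clones, 2):
        if edge_predicate(a, b, max_distance):
            edges.add(frozenset({clone_key(a), clone_key(b)}))
    return edges


def brute_force_components(clones, edges):
    parent = {clone_key(c): clone_key(c) for c in clones}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for edge in edges:
        a, b = tuple(edge)
        parent[find(a)] = find(b)
    groups = {}
    for key in parent:
        groups.setdefault(find(key), set()).add(key)
    return {frozenset(g) for g in groups.values()}


class TestDistance:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ("TGTGCAAGA", "TGTGCAAGG", 1),
            ("TGTGCAAGA", "TGTGCAAGA", 0),
            ("TGTGCAAGA", "TGTGCAAGAA", math.inf),
        ],
    )
    def test_distance(self, a, b, expected):
        assert cdr3_distance(a, b) == expected


class TestEdgeRule:
    def test_shared_genes_one_bp_apart_link(self):
        clones = _clone_table(
            [("IGHV1", "IGHJ1", "TGTGCAAGA", 5), ("IGHV1", "IGHJ1", "TGTGCAAGG", 2)]
        )
        net = build_network(clones, "IGH")
        assert net.graph.number_of_edges() == 1

    def test_disjoint_j_sets_do_not_link(self):
        clones = _clone_table(
            [("IGHV1", "IGHJ1", "TGTGCAAGA", 5), ("IGHV1", "IGHJ2", "TGTGCAAGG", 2)]
        )
        net = build_network(clones, "IGH")
        assert net.graph.number_of_edges() == 0

    def test_ambiguous_multigene_calls_can_link(self):
        clones = _clone_table(
            [
                ("IGHV1,IGHV2", "IGHJ1", "TGTGCAAGA", 5),
                ("IGHV2,IGHV3", "IGHJ1,IGHJ2", "TGTGCAAGG", 2),
            ]
        )
        net = build_network(clones, "IGH")
        assert net.graph.number_of_edges() == 1

    def test_indel_linking_only_when_enabled(self):
        clones = _clone_table(
            [("IGHV1", "IGHJ1", "TGTGCAAGA", 5), ("IGHV1", "IGHJ1", "TGTGCAAGGA", 2)]
        )
        assert build_network(clones, "IGH").graph.number_of_edges() == 0
        # one insertion apart: linked only under the opt-in indel rule
        indel = _clone_table(
            [("IGHV1", "IGHJ1", "TGTGCAAGA", 5), ("IGHV1", "IGHJ1", "TGTGGCAAGA", 2)]
        )
        assert build_network(indel, "IGH", allow_indel=True).graph.number_of_edges() == 1

    def test_display_size_cube_root_scaling(self):
        clones = _clone_table([("IGHV1", "IGHJ1", "TGTGCAAGA", 27),
                               ("IGHV1", "IGHJ2", "TGTACAAGA", 1)])
        net = build_network(clones, "IGH")
        sizes = {attrs["count"]: attrs["display_size"]
                 for _, attrs in net.graph.nodes(data=True)}
        assert sizes[27] / sizes[1] == pytest.approx(3.0)
        assert display_size(8 * 13) == pytest.approx(2 * display_size(13))

    @pytest.mark.parametrize("seed", range(20))
    def test_edge_set_matches_brute_force_oracle(self, seed):
        rnd = random.Random(seed)
        clones = random_clone_table(rnd, rnd.randint(20, 300))
        net = build_network(clones, "IGH")
        got = {frozenset(e) for e in net.graph.edges()}
        assert got == brute_force_edges(clones)


class TestClusters:
    def test_path_is_one_cluster(self):
        clones = _clone_table(
            [
                ("IGHV1", "IGHJ1", "TGTGCAAGA", 5),
                ("IGHV1", "IGHJ1", "TGTGCAAGG", 2),
                ("IGHV1", "IGHJ1", "TGTGCAAGC", 1),
            ]
        )
        net = build_network(clones, "IGH")
        clusters = find_clusters(net)
        assert len(clusters) == 1 and len(clusters[0].clones) == 3

    def test_isolated_nodes_are_singleton_clusters(self):
        clones = _clone_table(
            [("IGHV%d" % i, "IGHJ1", "TGTGCAAGA", 1) for i in range(1, 6)]
        )
        net = build_network(clones, "IGH")
        assert len(find_clusters(net)) == 5

    @pytest.mark.parametrize("seed", range(20))
    def test_partition_matches_union_find_oracle(self, seed):
        rnd = random.Random(seed + 1000)
        clones = random_clone_table(rnd, rnd.randint(20, 300))
        net = build_network(clones, "IGH")
        clusters = find_clusters(net)
        got = {frozenset(c.members) for c in clusters}
        expected = brute_force_components(clones, brute_force_edges(clones))
        assert got == expected

    def test_cluster_fractions_sum_to_one(self):
        rnd = random.Random(99)
        clones = random_clone_table(rnd, 100)
        clusters = find_clusters(build_network(clones, "IGH"))
        assert sum(c.fraction for c in clusters) == pytest.approx(1.0, abs=1e-9)
        filtered = filter_singleton_clusters(clusters, 2)
        assert sum(c.fraction for c in filtered) == pytest.approx(1.0, abs=1e-9)


class TestSingletonFilter:
    def test_filter_and_renormalize(self):
        clones = _clone_table(
            [
                ("IGHV1", "IGHJ1", "TGTGCAAGA", 1),
                ("IGHV2", "IGHJ1", "TGAACAAGA", 5),
                ("IGHV3", "IGHJ1", "TGGACAAGA", 1),
            ]
        )
        clusters = find_clusters(build_network(clones, "IGH"))
        kept = filter_singleton_clusters(clusters, 2)
        assert len(kept) == 1 and kept[0].fraction == 1.0

    def test_two_single_molecule_clones_survive_as_a_pair(self):
        clones = _clone_table(
            [("IGHV1", "IGHJ1", "TGTGCAAGA", 1), ("IGHV1", "IGHJ1", "TGTGCAAGG", 1)]
        )
        clusters = find_clusters(build_network(clones, "IGH"))
        kept = filter_singleton_clusters(clusters, 2)
        assert len(kept) == 1 and kept[0].cluster_reads == 2

    def test_everything_filtered_gives_empty_list(self):
        clones = _clone_table([("IGHV1", "IGHJ1", "TGTGCAAGA", 1)])
        clusters = find_clusters(build_network(clones, "IGH"))
        assert filter_singleton_clusters(clusters, 2) == []


class TestDominance:
    def _clusters(self, fractions):
        clones = []
        for i, f in enumerate(fractions):
            clones.append(("IGHV%d" % (i % 4 + 1), "IGHJ%d" % (i % 3 + 1),
                           _unique_cdr3(i), int(round(f * 10000))))
        clusters = find_clusters(build_network(_clone_table(clones), "IGH"))
        return score_dominance(clusters)

    def test_exactly_ten_percent_is_dominant(self):
        clusters = self._clusters([0.10, 0.90])
        assert all(c.dominant for c in clusters)

    def test_just_below_ten_percent_is_not_dominant(self):
        clusters = self._clusters([0.0999, 0.9001])
        assert sorted(c.dominant for c in clusters) == [False, True]

    def test_colors_assigned_in_descending_fraction_order(self):
        clusters = self._clusters([0.5, 0.3, 0.05, 0.05, 0.05, 0.05])
        by_fraction = sorted(clusters, key=lambda c: -c.fraction)
        assert [c.color for c in by_fraction[:2]] == ["red", "blue"]
        assert all(c.color == "gray" for c in by_fraction[2:])

    def test_invalid_threshold_rejected(self):
        with pytest.raises(UsageError):
            score_dominance([], theta=0.0)


def _unique_cdr3(i):
    # CDR3s pairwise length-distinct or far apart so no accidental links
    return "TGT" + "ACG" * (i + 2) + "AGA"


class TestClassification:
    def _label(self, fractions):
        clones = [
            ("IGHV%d" % (i % 4 + 1), "IGHJ%d" % (i % 3 + 1), _unique_cdr3(i),
             max(1, int(round(f * 10000))))
            for i, f in enumerate(fractions)
        ]
        clusters = score_dominance(find_clusters(build_network(_clone_table(clones), "IGH")))
        return classify_sample({"IGH": clusters}).sample_label

    def test_monoclonal(self):
        assert self._label([0.92, 0.02, 0.02, 0.02, 0.02]) == LABEL_MONO

    def test_biclonal(self):
        assert self._label([0.45, 0.30, 0.05, 0.05, 0.05, 0.05, 0.05]) == LABEL_BI

    def test_oligoclonal(self):
        assert self._label([0.20, 0.15, 0.12, 0.05] + [0.08] * 6) == LABEL_OLIGO

    def test_no_dominant_cluster(self):
        assert self._label([0.09] * 11 + [0.01]) == LABEL_NONE

    def test_scale_invariance(self):
        rnd = random.Random(5)
        table = [(("IGHV%d" % rnd.randint(1, 4)), "IGHJ1", _unique_cdr3(i),
                  rnd.randint(1, 60)) for i in range(20)]
        labels = []
        for factor in (1, 17):
            scaled = [(v, j, c, n * factor) for v, j, c, n in table]
            clusters = score_dominance(
                find_clusters(build_network(_clone_table(scaled), "IGH"))
            )
            labels.append(classify_sample({"IGH": clusters}).sample_label)
        assert labels[0] == labels[1]

    def test_light_group_reported_but_sample_label_from_heavy(self):
        heavy = _clone_table([("IGHV1", "IGHJ1", "TGTGCAAGA", 100)])
        light = clones_from_records(
            [
                ClonotypeRecord("s", "IGK", frozenset({"IGKV1"}), frozenset({"IGKJ1"}),
                                "TGCCAACAG", 50),
                ClonotypeRecord("s", "IGL", frozenset({"IGLV1"}), frozenset({"IGLJ1"}),
                                "TGCCAGCAG", 50),
            ]
        )["light"]
        by_group = {}
        for group, clones in (("IGH", heavy), ("light", light)):
            by_group[group] = score_dominance(
                find_clusters(build_network(clones, group))
            )
        result = classify_sample(by_group)
        assert result.sample_label == LABEL_MONO
        assert result.per_group["light"].label == LABEL_BI


class TestBranchingMetrics:
    def test_singleton_cluster(self):
        clones = _clone_table([("IGHV1", "IGHJ1", "TGTGCAAGA", 4)])
        net = build_network(clones, "IGH")
        (cluster,) = find_clusters(net)
        metrics = shm_branching_metrics(cluster, net)
        assert metrics == {
            "subclone_count": 0,
            "max_depth_from_major": 0,
            "max_degree": 0,
            "variant_read_fraction": 0.0,
        }

    def test_star_of_major_and_four_variants(self):
        root = "TGTGCAAGA"
        variants = ["AGTGCAAGA", "TCTGCAAGA", "TGAGCAAGA", "TGTGCAAGC"]
        clones = _clone_table(
            [("IGHV1", "IGHJ1", root, 20)] + [("IGHV1", "IGHJ1", v, 1) for v in variants]
        )
        net = build_network(clones, "IGH")
        (cluster,) = find_clusters(net)
        metrics = shm_branching_metrics(cluster, net)
        assert metrics["subclone_count"] == 4
        assert metrics["max_depth_from_major"] == 1
        assert metrics["max_degree"] == 4
        assert metrics["variant_read_fraction"] == pytest.approx(4 / 24)

    def test_major_clone_tie_breaks_to_lexicographic_cdr3(self):
        clones = _clone_table(
            [("IGHV1", "IGHJ1", "TGTGCAAGG", 5), ("IGHV1", "IGHJ1", "TGTGCAAGA", 5)]
        )
        (cluster,) = find_clusters(build_network(clones, "IGH"))
        assert cluster.major_clone.cdr3_nt == "TGTGCAAGA"
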