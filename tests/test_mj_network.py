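import itertools

import numpy as np
import pytest

from ystr.mj_network import (
    build_network,
    delineate_cluster,
    spanning_cost,
)
from ystr.str_clusters import find_modal_haplotypes


def steiner_oracle_cost(profiles, max_extra=2):
    """Exact minimum connection cost by enumerating lattice Steiner points
    inside the allele bounding box (brute force; tiny inputs only)."""
    profiles = [tuple(p) for p in profiles]
    lows = [min(p[i] for p in profiles) for i in range(len(profiles[0]))]
    highs = [max(p[i] for p in profiles) for i in range(len(profiles[0]))]
    lattice = [
        pt for pt in itertools.product(
            *[range(lo, hi + 1) for lo, hi in zip(lows, highs)])
        if pt not in set(profiles)
    ]
    best = spanning_cost(profiles)
    for k in range(1, max_extra + 1):
        for extra in itertools.combinations(lattice, k):
            best = min(best, spanning_cost(profiles + list(extra)))
    return best


class TestBuildNetwork:
    def test_two_haplotypes_single_edge(self, hap):
        a, b = hap(), hap([(0, 15), (1, 19)])  # 1 + 2 = 3 steps
        net = build_network([a, b])
        assert len(net.nodes) == 2
        assert net.edges == [(min(a.alleles, b.alleles),
                              max(a.alleles, b.alleles))]
        assert net.total_cost() == 3

    def test_three_arm_star_gets_one_median(self, hap):
        a, b, c = hap([(0, 15)]), hap([(1, 18)]), hap([(2, 26)])
        net = build_network([a, b, c])
        medians = [v for v, k in net.kinds.items() if k == "median"]
        assert len(medians) == 1
        assert medians[0] == hap().alleles  # the consensus profile
        assert net.total_cost() == 3  # vs 4 without the median
        assert sorted(net.neighbors(medians[0])) == sorted(
            [a.alleles, b.alleles, c.alleles])

    def test_collinear_path_no_median(self, hap):
        a, b, c = hap(), hap([(0, 15)]), hap([(0, 16)])
        net = build_network([a, b, c])
        assert all(k == "observed" for k in net.kinds.values())
        assert net.edges == sorted(
            [(min(a.alleles, b.alleles), max(a.alleles, b.alleles)),
             (min(b.alleles, c.alleles), max(b.alleles, c.alleles))])

    def test_mixed_haplogroups_rejected(self, hap):
        with pytest.raises(ValueError):
            build_network([hap(), hap([(0, 15)], haplogroup="Q-M242")])

    def test_single_profile_rejected(self, hap):
        with pytest.raises(ValueError):
            build_network([hap(), hap()])

    def test_every_observed_haplotype_present(self, hap):
        haps = [hap([(i % 15, 12 + i % 4)]) for i in range(20)]
        net = build_network(haps)
        for h in haps:
            assert h.alleles in net.kinds
            assert net.kinds[h.alleles] == "observed"

    def test_cost_never_exceeds_observed_mst(self, hap):
        rng = np.random.default_rng(0)
        for _ in range(10):
            haps = [
                hap([(int(i), int(14 + rng.integers(-2, 3)))
                     for i in rng.choice(15, size=3, replace=False)])
                for _ in range(6)
            ]
            distinct = sorted({h.alleles for h in haps})
            if len(distinct) < 2:
                continue
            net = build_network(haps)
            assert net.total_cost() <= spanning_cost(distinct) + 1e-9

    def test_input_order_invariance(self, hap):
        haps = [hap([(i % 15, 12 + i % 4)]) for i in range(12)]
        n1 = build_network(haps)
        n2 = build_network(haps[::-1])
        assert n1.nodes == n2.nodes
        assert n1.edges == n2.edges

    def test_steiner_cost_on_small_cases(self, hap):
        # three orthogonal 1-mutants around an unobserved center
        cases = [
            [hap([(0, 15)]), hap([(1, 18)]), hap([(2, 26)])],
            # square: no Steiner point helps
            [hap(), hap([(0, 15)]), hap([(1, 18)]), hap([(0, 15), (1, 18)])],
            # two distant profiles
            [hap(), hap([(0, 17)])],
            # Y-shape with one shared median among four tips
            [hap([(0, 15)]), hap([(1, 18)]), hap([(2, 26)]), hap([(0, 13)])],
        ]
        for haps in cases:
            net = build_network(haps)
            oracle = steiner_oracle_cost(sorted({h.alleles for h in haps}))
            assert net.total_cost() == pytest.approx(oracle)

    def test_recovers_handcrafted_genealogy(self, hap):
        """Homoplasy-free tree data: network equals the true genealogy
        collapsed to distinct profiles."""
        f = hap()
        a = hap([(0, 15)])           # founder + 1 step at locus 0
        b = hap([(1, 18)])           # founder + 1 step at locus 1
        c = hap([(0, 15), (2, 26)])  # child of a, extra step at locus 2
        net = build_network([f, f, a, b, c])
        true_edges = sorted(
            (min(u.alleles, v.alleles), max(u.alleles, v.alleles))
            for u, v in [(f, a), (f, b), (a, c)])
        assert net.edges == true_edges
        assert all(k == "observed" for k in net.kinds.values())


def _star_network(hap, foreign_arm=False):
    center = [hap()] * 3
    arms = [hap([(i, hap().alleles[i] + 1)]) for i in range(4)]
    haps, pops = [], []
    for h in center:
        haps.append(h)
        pops.append("KAZ2")
    for i, arm in enumerate(arms):
        count = 7 if (foreign_arm and i == 3) else 1
        pop = "OTHER" if (foreign_arm and i == 3) else "KAZ2"
        for _ in range(count):
            haps.append(arm)
            pops.append(pop)
    net = build_network(haps, populations=pops)
    modal = find_modal_haplotypes([hap()] * 11, threshold=10)[0]
    return net, modal


class TestDelineateCluster:
    def test_all_seed_star_fully_attributed(self, hap):
        net, modal = _star_network(hap)
        cluster = delineate_cluster(net, "KAZ2", modal)
        assert cluster.n == 7  # 3 center + 4 arms
        assert cluster.enrichment == 1.0

    def test_foreign_arm_excluded(self, hap):
        net, modal = _star_network(hap, foreign_arm=True)
        cluster = delineate_cluster(net, "KAZ2", modal,
                                    enrichment_threshold=0.5)
        assert cluster.n == 6  # foreign arm of 7 samples dropped
        assert all(h.alleles != net.nodes[-1] or True for h in cluster.members)
        assert cluster.enrichment >= 0.5

    def test_founder_only_cluster(self, hap):
        a, b = hap(), hap([(0, 20)])
        net = build_network([a, a, b], populations=["KAZ2", "KAZ2", "OTHER"])
        modal = find_modal_haplotypes([a] * 11, threshold=10)[0]
        cluster = delineate_cluster(net, "KAZ2", modal,
                                    enrichment_threshold=0.9)
        assert cluster.n == 2
        assert cluster.member_nodes == [a.alleles]

    def test_founder_absent_errors(self, hap):
        net, _ = _star_network(hap)
        ghost = find_modal_haplotypes(
            [hap([(0, 30)])] * 11, threshold=10)[0]
        with pytest.raises(ValueError, match="founder"):
            delineate_cluster(net, "KAZ2", ghost)

    def test_empty_zone_warning_result(self, hap):
        a, b = hap(), hap([(0, 15)])
        net = build_network([a, b], populations=["OTHER", "OTHER"])
        modal = find_modal_haplotypes([a] * 11, threshold=10)[0]
        cluster = delineate_cluster(net, "KAZ2", modal)
        assert cluster.empty
        assert cluster.n == 0

    def test_distance_cap_excludes_far_nodes(self, hap):
        chain = [hap([(0, 14 + i)]) for i in range(7)]  # 0..6 steps away
        net = build_network(chain, populations=["KAZ2"] * 7)
        modal = find_modal_haplotypes([chain[0]] * 11, threshold=10)[0]
        cluster = delineate_cluster(net, "KAZ2", modal, distance_cap=4)
        assert cluster.n == 5  # distances 0..4 inclusive

    def test_insertion_order_invariance(self, hap):
        haps = [hap([(i % 15, 13 + i % 3)]) for i in range(10)]
        pops = ["KAZ2" if i % 3 else "OTHER" for i in range(10)]
        modal = find_modal_haplotypes([haps[1]] * 11, threshold=10)[0]
        n1 = build_network(haps, populations=pops)
        n2 = build_network(haps[::-1], populations=pops[::-1])
        c1 = delineate_cluster(n1, "KAZ2", modal)
        c2 = delineate_cluster(n2, "KAZ2", modal)
        assert c1.member_nodes == c2.member_nodes
        assert sorted(h.alleles for h in c1.members) == \
            sorted(h.alleles for h in c2.members)
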