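import itertools

import numpy as np
import pytest

from ystr.amova_mantel import (
    GroupingScheme,
    amova,
    amova_oracle_ss,
    mantel,
)
from ystr.data_io import SampleRecord
from ystr.popgen_distance import DistanceMatrix


def _records(layout):
    """layout: list of (population, haplogroup) pairs."""
    return [SampleRecord(f"s{i}", pop, haplogroup=hg)
            for i, (pop, hg) in enumerate(layout)]


def _scheme(assignment, name="scheme"):
    return GroupingScheme(name=name, assignment=assignment)


FOUR_POP_SCHEME = _scheme({"P1": "G1", "P2": "G1", "P3": "G2", "P4": "G2"})


class TestAmova:
    def test_no_variation_flag(self):
        recs = _records([(f"P{p}", "A") for p in (1, 2, 3, 4)
                         for _ in range(5)])
        res = amova(recs, FOUR_POP_SCHEME, n_perm=9, seed=0)
        assert res.no_variation
        assert res.sigma2 == (0.0, 0.0, 0.0)

    def test_maximal_between_group_divergence(self):
        layout = [("P1", "A")] * 5 + [("P2", "A")] * 5 \
            + [("P3", "B")] * 5 + [("P4", "B")] * 5
        res = amova(_records(layout), FOUR_POP_SCHEME, n_perm=9, seed=0)
        assert res.pct_within_populations == pytest.approx(0.0, abs=1e-9)
        assert res.pct_among_populations_within_groups == pytest.approx(
            0.0, abs=1e-9)
        assert res.pct_among_groups == pytest.approx(100.0, abs=1e-9)
        assert res.phi_st == pytest.approx(1.0)

    def _mixed_layout(self, seed=5, pops=4, per_pop=6):
        rng = np.random.default_rng(seed)
        layout = []
        for p in range(pops):
            for _ in range(per_pop):
                layout.append((f"P{p + 1}", "ABC"[rng.integers(0, 3)]))
        return layout

    def test_components_match_distance_matrix_oracle(self):
        """Count-based components vs explicit sums of squares over the
        24x24 0/1 distance matrix, then the same n-coefficient algebra."""
        layout = self._mixed_layout()
        recs = _records(layout)
        res = amova(recs, FOUR_POP_SCHEME, n_perm=9, seed=0)

        pops = sorted({p for p, _ in layout})
        pop_of = [pops.index(p) for p, _ in layout]
        group_of_pop = [0, 0, 1, 1]
        n = len(layout)
        d = np.array([[0.0 if layout[i][1] == layout[j][1] else 1.0
                       for j in range(n)] for i in range(n)])
        ss_a, ss_b, ss_w = amova_oracle_ss(d, pop_of, group_of_pop)

        sizes = np.array([6.0] * 4)
        big_n, n_groups, n_pops = 24.0, 2, 4
        group_sizes = np.array([12.0, 12.0])
        df = (n_groups - 1, n_pops - n_groups, int(big_n) - n_pops)
        sum_np2_over_ng = sum(
            (sizes[np.array(group_of_pop) == g] ** 2).sum() / group_sizes[g]
            for g in range(n_groups))
        n_c = (big_n - sum_np2_over_ng) / df[1]
        n_b = (sum_np2_over_ng - (sizes ** 2).sum() / big_n) / df[0]
        n_a = (big_n - (group_sizes ** 2).sum() / big_n) / df[0]
        sigma_c = ss_w / df[2]
        sigma_b = (ss_b / df[1] - sigma_c) / n_c
        sigma_a = (ss_a / df[0] - sigma_c - n_b * sigma_b) / n_a

        assert res.sigma2[0] == pytest.approx(sigma_a, abs=1e-9)
        assert res.sigma2[1] == pytest.approx(sigma_b, abs=1e-9)
        assert res.sigma2[2] == pytest.approx(sigma_c, abs=1e-9)

    def test_percentages_sum_to_100_even_when_negative(self):
        layout = self._mixed_layout(seed=11)
        res = amova(_records(layout), FOUR_POP_SCHEME, n_perm=9, seed=0)
        total = (res.pct_within_populations
                 + res.pct_among_populations_within_groups
                 + res.pct_among_groups)
        assert total == pytest.approx(100.0, abs=1e-6)

    def test_negative_components_retained(self):
        # scan seeds for a draw with a negative among-group component
        for seed in range(40):
            layout = self._mixed_layout(seed=seed)
            res = amova(_records(layout), FOUR_POP_SCHEME, n_perm=9, seed=0)
            if res.pct_among_groups < 0:
                total = (res.pct_within_populations
                         + res.pct_among_populations_within_groups
                         + res.pct_among_groups)
                assert total == pytest.approx(100.0, abs=1e-6)
                return
        pytest.fail("no negative component found across seeds")

    def test_sample_order_invariance(self):
        layout = self._mixed_layout(seed=7)
        res1 = amova(_records(layout), FOUR_POP_SCHEME, n_perm=0, seed=0)
        res2 = amova(_records(layout[::-1]), FOUR_POP_SCHEME, n_perm=0, seed=0)
        assert res1.sigma2 == pytest.approx(res2.sigma2)

    def test_haplogroup_relabelling_invariance(self):
        layout = self._mixed_layout(seed=7)
        relabel = {"A": "Z9", "B": "Q1", "C": "M0"}
        layout2 = [(p, relabel[h]) for p, h in layout]
        res1 = amova(_records(layout), FOUR_POP_SCHEME, n_perm=0, seed=0)
        res2 = amova(_records(layout2), FOUR_POP_SCHEME, n_perm=0, seed=0)
        assert res1.sigma2 == pytest.approx(res2.sigma2)

    def test_single_group_scheme_rejected(self):
        layout = self._mixed_layout()
        scheme = _scheme({f"P{i}": "G1" for i in range(1, 5)})
        with pytest.raises(ValueError):
            amova(_records(layout), scheme, n_perm=9, seed=0)

    def test_p_values_in_unit_interval(self):
        layout = self._mixed_layout(seed=3)
        res = amova(_records(layout), FOUR_POP_SCHEME, n_perm=99, seed=1)
        for p in res.p_values.values():
            assert 0.0 < p <= 1.0

    def test_seeded_permutations_reproducible(self):
        layout = self._mixed_layout(seed=3)
        r1 = amova(_records(layout), FOUR_POP_SCHEME, n_perm=49, seed=42)
        r2 = amova(_records(layout), FOUR_POP_SCHEME, n_perm=49, seed=42)
        assert r1.p_values == r2.p_values


def _matrix(values, n):
    d = np.zeros((n, n))
    iu = np.triu_indices(n, 1)
    d[iu] = values
    d += d.T
    return d


class TestMantel:
    def test_identity_r_one(self):
        d = _matrix([1.0, 2.0, 3.0], 3)
        dm = DistanceMatrix(list("abc"), d, "nei_genetic")
        res = mantel(dm, dm, n_perm=99, seed=0)
        assert res.r == pytest.approx(1.0)

    def test_exact_anti_order(self):
        a = DistanceMatrix(list("abc"), _matrix([1.0, 2.0, 3.0], 3),
                           "nei_genetic")
        b = DistanceMatrix(list("abc"), _matrix([3.0, 2.0, 1.0], 3),
                           "geographic_km")
        assert mantel(a, b, n_perm=9, seed=0).r == pytest.approx(-1.0)

    def test_p_matches_full_enumeration_at_n5(self):
        rng = np.random.default_rng(8)
        n = 5
        a = DistanceMatrix([f"p{i}" for i in range(n)],
                           _matrix(rng.uniform(1, 9, 10), n), "nei_genetic")
        b = DistanceMatrix([f"p{i}" for i in range(n)],
                           _matrix(rng.uniform(1, 9, 10), n), "geographic_km")
        iu = np.triu_indices(n, 1)
        x = a.d[iu]
        r_obs = float(np.corrcoef(x, b.d[iu])[0, 1])
        count = 0
        for perm in itertools.permutations(range(n)):
            yp = b.d[np.ix_(perm, perm)][iu]
            if abs(float(np.corrcoef(x, yp)[0, 1])) >= abs(r_obs) - 1e-12:
                count += 1
        p_exact = count / 120  # identity included

        res = mantel(a, b, n_perm=4999, seed=1)
        assert res.r == pytest.approx(r_obs, abs=1e-12)
        se = np.sqrt(p_exact * (1 - p_exact) / 4999)
        assert abs(res.p_value - p_exact) <= 4 * se + 1e-3

    def test_label_mismatch_rejected(self):
        a = DistanceMatrix(list("abc"), _matrix([1, 2, 3], 3), "nei_genetic")
        b = DistanceMatrix(list("abd"), _matrix([1, 2, 3], 3), "geographic_km")
        with pytest.raises(ValueError):
            mantel(a, b, n_perm=9, seed=0)

    def test_zero_variance_rejected(self):
        a = DistanceMatrix(list("abc"), _matrix([1, 1, 1], 3), "nei_genetic")
        b = DistanceMatrix(list("abc"), _matrix([1, 2, 3], 3), "geographic_km")
        with pytest.raises(ValueError):
            mantel(a, b, n_perm=9, seed=0)
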