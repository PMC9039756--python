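import itertools
import math

import numpy as np
import pytest
from scipy import stats

from xreact.core import GeneModel, GenomicInterval, RepeatElement, SignalTrack
from xreact.features import (
    count_cpg_upstream,
    count_repeats_near_tss,
    distance_to_nearest,
    mann_whitney,
    metagene_profile,
    stratify_lines,
)


def _gene(strand, tss, length=10_000, gene_id="g"):
    if strand == "+":
        iv = GenomicInterval("chrX", tss, tss + length, "+")
    else:
        iv = GenomicInterval("chrX", tss - length + 1, tss + 1, "-")
    return GeneModel(gene_id, gene_id, iv)


def _repeat(mid, length=200, rclass="SINE", age=None):
    start = mid - length // 2
    return RepeatElement(
        GenomicInterval("chrX", start, start + length), rclass, "fam", length, age
    )


class TestCpgCounting:
    def test_window_boundaries(self):
        gene = _gene("+", 10_000)
        cpgs = np.array([8100, 9000, 9999])
        assert count_cpg_upstream(gene, cpgs) == 3

    def test_tss_itself_excluded(self):
        gene = _gene("+", 10_000)
        assert count_cpg_upstream(gene, np.array([10_000])) == 0
        assert count_cpg_upstream(gene, np.array([7999])) == 0

    def test_no_cpgs(self):
        assert count_cpg_upstream(_gene("+", 10_000), np.array([], dtype=np.int64)) == 0


class TestRepeatCounting:
    def test_closed_window_boundaries(self):
        tss = 1_000_000
        gene = _gene("+", tss)
        reps = [_repeat(tss - 100_000), _repeat(tss + 100_000)]
        assert count_repeats_near_tss(gene, reps, "SINE") == 2

    def test_other_class_excluded(self):
        gene = _gene("+", 1_000_000)
        reps = [_repeat(1_000_000, rclass="LINE", age=1)]
        assert count_repeats_near_tss(gene, reps, "SINE") == 0
        assert count_repeats_near_tss(gene, reps, "LINE") == 1

    def test_midpoint_rule_straddling_element(self):
        tss = 1_000_000
        gene = _gene("+", tss)
        # element crosses the window edge but its midpoint lies outside
        rep = _repeat(tss + 100_400, length=1000)
        assert count_repeats_near_tss(gene, [rep], "SINE") == 0

    def test_class_sum_equals_total(self):
        rng = np.random.default_rng(1)
        gene = _gene("+", 1_000_000)
        reps = [
            _repeat(int(m), rclass=("SINE" if rng.random() < 0.5 else "LINE"), age=1)
            for m in rng.integers(850_000, 1_150_000, size=100)
        ]
        total = count_repeats_near_tss(gene, reps, None)
        assert (
            count_repeats_near_tss(gene, reps, "SINE")
            + count_repeats_near_tss(gene, reps, "LINE")
            == total
        )


class TestLineStratification:
    def test_size_boundary_inclusive(self):
        lines = [
            _repeat(10_000, length=6000, rclass="LINE", age=1),
            _repeat(50_000, length=5999, rclass="LINE", age=2),
            _repeat(90_000, length=300, rclass="SINE"),
        ]
        strata = stratify_lines(lines, by="size")
        assert [r.length_bp for r in strata["full_length"]] == [6000]
        assert [r.length_bp for r in strata["short"]] == [5999]

    def test_age_mode_requires_rank(self):
        lines = [_repeat(10_000, length=1000, rclass="LINE", age=None)]
        with pytest.raises(ValueError, match="without age_rank"):
            stratify_lines(lines, by="age")

    def test_age_mode_groups(self):
        lines = [
            _repeat(10_000, length=1000, rclass="LINE", age=2),
            _repeat(20_000, length=1000, rclass="LINE", age=1),
            _repeat(30_000, length=1000, rclass="LINE", age=1),
        ]
        strata = stratify_lines(lines, by="age")
        assert {a: len(rs) for a, rs in strata.items()} == {1: 2, 2: 1}


class TestDistanceToNearest:
    def test_min_distance(self):
        gene = _gene("+", 5_000_000)
        anchors = [("e1", 4_000_000), ("e2", 7_500_000)]
        assert distance_to_nearest(gene, anchors) == 1_000_000

    def test_self_exclusion(self):
        gene = _gene("+", 5_000_000, gene_id="e1")
        assert math.isnan(distance_to_nearest(gene, [("e1", 5_000_000)]))

    def test_single_anchor(self):
        gene = _gene("+", 5_000_000)
        assert distance_to_nearest(gene, [("xist", 103_460_000)]) == 98_460_000

    def test_lipschitz_in_tss(self):
        anchors = [(f"a{i}", int(p)) for i, p in
                   enumerate(np.random.default_rng(2).integers(0, 10**7, 20))]
        prev = None
        for tss in range(1_000_000, 1_010_000, 500):
            d = distance_to_nearest(_gene("+", tss), anchors)
            if prev is not None:
                assert abs(d - prev) <= 500
            prev = d


class TestMannWhitney:
    def test_exact_separated_groups(self):
        """Full enumeration of C(6,3)=20 orderings gives p = 2/20."""
        res = mann_whitney([1, 2, 3], [4, 5, 6], mode="exact")
        assert res.u_statistic == 0
        assert res.p_value == pytest.approx(0.1)
        assert res.direction == "b_higher"

    def test_identical_multisets(self):
        res = mann_whitney([1, 2, 2, 3], [1, 2, 2, 3], mode="exact")
        assert res.p_value == pytest.approx(1.0)

    def test_single_observations(self):
        res = mann_whitney([1], [2], mode="exact")
        assert res.p_value == pytest.approx(1.0)

    def test_all_identical_values(self):
        res = mann_whitney([5, 5], [5, 5, 5])
        assert res.p_value == 1.0 and res.direction == "none"

    def test_exact_vs_normal_n20(self):
        """Exact and normal-approximation p agree closely for untied n=20."""
        rng = np.random.default_rng(3)
        for _ in range(10):
            a = rng.normal(0, 1, 20)
            b = rng.normal(0.3, 1, 20)
            pe = mann_whitney(a, b, mode="exact").p_value
            pn = mann_whitney(a, b, mode="normal").p_value
            assert abs(pe - pn) < 0.01

    def test_exact_enumeration_with_ties(self):
        """Tied data: p matches brute-force enumeration of assignments."""
        a, b = [1.0, 2.0, 2.0], [2.0, 3.0, 4.0]
        res = mann_whitney(a, b, mode="exact")
        pooled = np.array(a + b)
        ranks = stats.rankdata(pooled)
        n1 = len(a)
        mu = n1 * len(b) / 2
        u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
        hits = total = 0
        for combo in itertools.combinations(range(6), 3):
            u = sum(ranks[i] for i in combo) - n1 * (n1 + 1) / 2
            total += 1
            if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
                hits += 1
        assert res.p_value == pytest.approx(hits / total)


class TestMetageneProfile:
    def _const_track(self, value, lo=0, hi=1_000_000):
        return SignalTrack("chrX", [lo], [hi], [value])

    def test_constant_track_conserved(self):
        gene = _gene("+", 100_000)
        prof = metagene_profile([gene], self._const_track(3.5))
        assert np.allclose(prof, 3.5)
        prof_body = metagene_profile([gene], self._const_track(3.5), mode="scaled_body")
        assert np.allclose(prof_body, 3.5)

    def test_strand_mirroring(self):
        """A delta-like peak at the TSS lands in the same bin either strand."""
        tss = 100_000
        track = SignalTrack("chrX", [tss - 25], [tss + 25], [10.0])
        p_plus = metagene_profile([_gene("+", tss)], track)
        p_minus = metagene_profile([_gene("-", tss)], track)
        assert np.argmax(p_plus) in (59, 60)
        assert np.allclose(p_plus, p_minus[::-1]) or np.allclose(p_plus, p_minus)

    def test_linearity_across_genes(self):
        g1, g2 = _gene("+", 100_000, gene_id="a"), _gene("+", 500_000, gene_id="b")
        track = SignalTrack(
            "chrX", [0, 400_000], [200_000, 600_000], [2.0, 6.0]
        )
        prof = metagene_profile([g1, g2], track)
        assert np.allclose(prof, 4.0)

    def test_short_gene_skipped(self):
        long_gene = _gene("+", 100_000, length=10_000, gene_id="long")
        short = GeneModel("short", "short",
                          GenomicInterval("chrX", 50_000, 50_050, "+"))
        prof = metagene_profile([long_gene, short], self._const_track(1.0),
                                mode="scaled_body")
        assert np.allclose(prof, 1.0)

    def test_empty_gene_list_errors(self):
        with pytest.raises(ValueError, match="empty"):
            metagene_profile([], self._const_track(1.0))
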