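import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from xreact.core import GeneModel, GenomicInterval, RepeatElement
from xreact.methylation import (
    cluster_promoters,
    differential_methylation,
    normalize_methylation,
    promoter_regions,
    repeat_flank_methylation,
)


def _gene(tss, gene_id, strand="+"):
    return GeneModel(gene_id, gene_id,
                     GenomicInterval("chrX", tss, tss + 5000, strand))


def _counts(rows):
    return pd.DataFrame(
        rows, columns=["region_id", "sample_id", "condition", "count"]
    )


class TestPromoterRegions:
    def test_window(self):
        reg = promoter_regions([_gene(10_000, "a")], flank_bp=1000)
        assert (reg.loc[0, "start"], reg.loc[0, "end"]) == (9000, 11_000)

    def test_zero_flank_rejected(self):
        with pytest.raises(ValueError, match="flank"):
            promoter_regions([_gene(10_000, "a")], flank_bp=0)

    def test_shared_tss_distinct_regions(self):
        reg = promoter_regions([_gene(10_000, "a"), _gene(10_000, "b")])
        assert reg["region_id"].is_unique
        assert (reg["start"] == 9000).all()


class TestNormalization:
    def test_cpm(self):
        rows = [("r1", "s1", "control", 250)]
        rows += [(f"x{i}", "s1", "control", c) for i, c in
                 enumerate([999_750])]
        out = normalize_methylation(_counts(rows))
        assert out.loc[0, "rate_cpm"] == pytest.approx(250.0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        rows = [(f"r{i}", "s1", "control", int(c))
                for i, c in enumerate(rng.integers(1, 100, 30))]
        base = normalize_methylation(_counts(rows))
        doubled = _counts([(r, s, c, n * 2) for r, s, c, n in rows])
        out = normalize_methylation(doubled)
        assert np.allclose(base["rate_cpm"], out["rate_cpm"])

    def test_single_region(self):
        out = normalize_methylation(_counts([("only", "s1", "control", 7)]))
        assert out.loc[0, "rate_cpm"] == pytest.approx(1e6)

    def test_zero_total_sample_named(self):
        with pytest.raises(ValueError, match="s2"):
            normalize_methylation(
                _counts([("r", "s1", "control", 5), ("r", "s2", "control", 0)])
            )


def _diff_table(control_counts, treated_counts, background=1_000_000):
    rows = []
    for rep, c in enumerate(control_counts, 1):
        rows.append(("r1", f"c{rep}", "control", c))
        rows.append(("bg", f"c{rep}", "control", background))
    for rep, c in enumerate(treated_counts, 1):
        rows.append(("r1", f"t{rep}", "tomato_high", c))
        rows.append(("bg", f"t{rep}", "tomato_high", background))
    return _counts(rows)


class TestDifferentialMethylation:
    def test_hypomethylation_called(self):
        """Large drop in a region's share: flagged lower; Fisher oracle
        agrees on the pooled table."""
        table = _diff_table([500], [100])
        res = differential_methylation(table).set_index("region_id")
        _, p_oracle = stats.fisher_exact([[500, 1_000_000], [100, 1_000_000]])
        assert p_oracle < 1e-6
        assert res.loc["r1", "p_value"] < 1e-6
        assert bool(res.loc["r1", "significantly_lower"])

    def test_identical_tables_null(self):
        res = differential_methylation(_diff_table([500], [500])).set_index("region_id")
        assert res.loc["r1", "p_value"] > 0.9
        assert not bool(res.loc["r1", "significantly_lower"])

    def test_increase_not_flagged_lower(self):
        res = differential_methylation(_diff_table([100], [500])).set_index("region_id")
        assert res.loc["r1", "p_value"] < 1e-6
        assert not bool(res.loc["r1", "significantly_lower"])

    def test_zero_both_conditions_untested(self):
        res = differential_methylation(_diff_table([0], [0])).set_index("region_id")
        assert math.isnan(res.loc["r1", "p_value"])
        assert not bool(res.loc["r1", "significantly_lower"])

    def test_missing_condition_errors(self):
        with pytest.raises(ValueError, match="absent"):
            differential_methylation(
                _counts([("r", "s", "control", 5)]), "control", "tomato_high"
            )

    def test_fisher_oracle_agreement_random_tables(self):
        """Call agreement with Fisher exact on >= 95% of random pooled tables."""
        rng = np.random.default_rng(5)
        agree = total = 0
        for _ in range(200):
            a, c = rng.integers(0, 400, 2)
            ta, tc = rng.integers(10_000, 50_000, 2)
            table = _diff_table([int(a)], [int(c)], background=0)
            table.loc[table.region_id == "bg", "count"] = [int(ta), int(tc)]
            res = differential_methylation(table).set_index("region_id")
            p_impl = res.loc["r1", "p_value"]
            _, p_f = stats.fisher_exact([[a, ta], [c, tc]])
            total += 1
            agree += (p_impl < 0.05) == (p_f < 0.05)
        assert agree / total >= 0.95


class TestClustering:
    def _rates(self, mat, statuses):
        rows = []
        for i, vals in enumerate(mat):
            for j, v in enumerate(vals):
                rows.append((f"prom_g{i}", f"g{i}", f"s{j}", v))
        return pd.DataFrame(
            rows, columns=["region_id", "gene_id", "sample_id", "rate_cpm"]
        )

    def _classes(self, statuses):
        return pd.DataFrame(
            {"gene_id": [f"g{i}" for i in range(len(statuses))], "status": statuses}
        )

    def test_planted_blocks_perfect_purity(self):
        rng = np.random.default_rng(0)
        # the two blocks differ in their pattern across samples (demethylated
        # in the last three samples vs constant), which survives z-scoring
        pattern_a = np.array([10, 10, 10, 2, 2, 2], dtype=float)
        pattern_b = np.array([2, 2, 2, 10, 10, 10], dtype=float)
        mat = np.vstack(
            [pattern_a + rng.normal(0, 0.1, (8, 6)),
             pattern_b + rng.normal(0, 0.1, (8, 6))]
        )
        statuses = ["reactivated"] * 8 + ["non_reactivated"] * 8
        res = cluster_promoters(
            self._rates(mat, statuses), self._classes(statuses), seed=1
        )
        assert res["purity"] == pytest.approx(1.0)
        assert res["permutation_p"] < 0.01

    def test_random_labels_not_significant(self):
        rng = np.random.default_rng(1)
        mat = rng.normal(0, 1, (24, 6))
        statuses = ["reactivated" if i % 3 == 0 else "non_reactivated"
                    for i in range(24)]
        res = cluster_promoters(
            self._rates(mat, statuses), self._classes(statuses), seed=2
        )
        assert res["permutation_p"] > 0.05

    def test_constant_matrix_missing_purity(self):
        mat = np.ones((6, 4))
        statuses = ["reactivated"] * 3 + ["non_reactivated"] * 3
        res = cluster_promoters(
            self._rates(mat, statuses), self._classes(statuses), seed=0
        )
        assert math.isnan(res["purity"])

    def test_too_few_regions(self):
        mat = np.ones((2, 4))
        statuses = ["reactivated", "non_reactivated"]
        with pytest.raises(ValueError, match="at least 4"):
            cluster_promoters(self._rates(mat, statuses), self._classes(statuses))


class TestRepeatFlank:
    def _setup(self):
        genes = [_gene(100_000, "re1"), _gene(400_000, "re2"),
                 _gene(700_000, "nr1"), _gene(1_000_000, "nr2")]
        classes = pd.DataFrame(
            {"gene_id": ["re1", "re2", "nr1", "nr2"],
             "status": ["reactivated", "reactivated",
                        "non_reactivated", "non_reactivated"]}
        )
        return genes, classes

    @staticmethod
    def _sines_near(tss, n=3):
        return [
            RepeatElement(GenomicInterval("chrX", tss - 10_000 + i * 3000,
                                          tss - 9800 + i * 3000), "SINE", "B1", 200)
            for i in range(n)
        ]

    def test_empty_flank_counts_rate_zero(self):
        genes, classes = self._setup()
        reps = sum((self._sines_near(g.tss) for g in genes), [])
        # counted regions lie far away from every flank
        counts = _counts([("far", "s1", "control", 100)])
        counts["start"], counts["end"] = 5_000_000, 5_001_000
        comps = repeat_flank_methylation(reps, counts, classes, genes)
        assert comps[0].p_value == 1.0  # all rates zero -> identical groups

    def test_single_element_class_skipped(self):
        genes, classes = self._setup()
        reps = [RepeatElement(GenomicInterval("chrX", 90_000, 90_200),
                              "LINE", "L1", 200, 1)]
        counts = _counts([("far", "s1", "control", 100)])
        counts["start"], counts["end"] = 5_000_000, 5_001_000
        assert repeat_flank_methylation(reps, counts, classes, genes) == []
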