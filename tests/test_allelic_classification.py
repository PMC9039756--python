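import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from xreact.classify import (
    allelic_ratio,
    betabinom_lrt,
    classify_escapees,
    classify_genes,
    delta_ratio_profile,
    filter_informative,
    fisher_pooled_test,
    rank_reactivated,
    validate_count_table,
)
from xreact.classify import test_reactivation as reactivation_test


def _table(rows):
    return pd.DataFrame(
        rows, columns=["gene_id", "condition", "replicate", "cast_count", "bl6_count"]
    )


def _gene_rows(gid, control, treated):
    rows = []
    for i, (c, b) in enumerate(control, 1):
        rows.append((gid, "control", i, c, b))
    for i, (c, b) in enumerate(treated, 1):
        rows.append((gid, "tomato_high", i, c, b))
    return rows


class TestAllelicRatio:
    @pytest.mark.parametrize(
        "cast,bl6,expected", [(5, 5, 0.5), (0, 10, 0.0), (19, 81, 0.19)]
    )
    def test_arithmetic(self, cast, bl6, expected):
        assert allelic_ratio(cast, bl6) == pytest.approx(expected)

    def test_zero_total_is_missing_not_error(self):
        assert math.isnan(allelic_ratio(0, 0))

    @settings(derandomize=True, max_examples=50)
    @given(cast=st.integers(0, 10_000), bl6=st.integers(0, 10_000))
    def test_bounds(self, cast, bl6):
        r = allelic_ratio(cast, bl6)
        assert math.isnan(r) or 0.0 <= r <= 1.0


class TestFilterInformative:
    def test_retained_and_dropped(self):
        rows = _gene_rows("keep", [(2, 10), (1, 10), (3, 10)], [(2, 10), (1, 10), (3, 10)])
        rows += _gene_rows("drop", [(2, 10), (1, 10), (3, 10)], [(1, 1), (0, 1), (0, 0)])
        got = filter_informative(_table(rows), 10, ("control", "tomato_high"))
        assert got == {"keep"}

    def test_unknown_condition_errors(self):
        rows = _gene_rows("g", [(1, 1)], [(1, 1)])
        with pytest.raises(ValueError, match="unknown condition"):
            filter_informative(_table(rows), 10, ("control", "nope"))

    def test_duplicate_rows_rejected(self):
        rows = _gene_rows("g", [(1, 1)], [(1, 1)]) * 2
        with pytest.raises(ValueError, match="duplicate"):
            validate_count_table(_table(rows))


class TestEscapees:
    def test_mean_replicate_ratio(self):
        rows = _gene_rows("esc", [(20, 80), (25, 75), (15, 85)], [(1, 1)] * 3)
        rows += _gene_rows("sil", [(1, 99)] * 3, [(1, 1)] * 3)
        got = classify_escapees(_table(rows), {"esc", "sil"}, 0.10)
        assert got == {"esc"}

    @settings(derandomize=True, max_examples=30)
    @given(thresholds=st.lists(st.floats(0.01, 0.9), min_size=2, max_size=2))
    def test_monotone_in_threshold(self, thresholds):
        """Raising the escape threshold never adds escapees."""
        rng = np.random.default_rng(0)
        rows = []
        for i in range(20):
            ratios = rng.uniform(0, 0.5, size=3)
            rows += _gene_rows(
                f"g{i}",
                [(int(100 * r), 100 - int(100 * r)) for r in ratios],
                [(1, 1)] * 3,
            )
        table = _table(rows)
        genes = {f"g{i}" for i in range(20)}
        lo, hi = sorted(thresholds)
        assert classify_escapees(table, genes, hi) <= classify_escapees(table, genes, lo)


class TestReactivationTest:
    def test_strong_reactivation_called(self):
        """LRT agrees with the Fisher-on-pooled oracle on a clear effect."""
        control = [(1, 99), (0, 100), (2, 98)]
        treated = [(30, 70), (28, 72), (33, 67)]
        p_fisher = fisher_pooled_test(
            [c for c, _ in control], [c + b for c, b in control],
            [c for c, _ in treated], [c + b for c, b in treated],
        )
        assert p_fisher < 1e-6
        res = reactivation_test(
            _table(_gene_rows("g", control, treated)), {"g"}, alpha=0.05
        )
        assert bool(res.loc[0, "reactivated"]) and res.loc[0, "p_value"] < 1e-6

    def test_null_identity(self):
        counts = [(10, 90), (12, 88), (9, 91)]
        res = reactivation_test(_table(_gene_rows("g", counts, counts)), {"g"})
        assert res.loc[0, "p_value"] > 0.9
        assert not res.loc[0, "reactivated"]

    def test_direction_filter(self):
        """A significant decrease is never called reactivated."""
        control = [(30, 70), (28, 72), (33, 67)]
        treated = [(1, 99), (0, 100), (2, 98)]
        res = reactivation_test(_table(_gene_rows("g", control, treated)), {"g"})
        assert res.loc[0, "p_value"] < 1e-6 and res.loc[0, "delta_ratio"] < 0
        assert not res.loc[0, "reactivated"]

    def test_zero_reads_condition_missing_p(self):
        res = reactivation_test(
            _table(_gene_rows("g", [(0, 0)] * 3, [(10, 10)] * 3)), {"g"}
        )
        assert math.isnan(res.loc[0, "p_value"]) and not res.loc[0, "reactivated"]


class TestRanking:
    def _classes(self, triples):
        return pd.DataFrame(
            [
                (gid, "reactivated", p, d)
                for gid, p, d in triples
            ],
            columns=["gene_id", "status", "p_value", "delta_ratio"],
        )

    def test_count_above_reference(self):
        cls = self._classes([("a", 1e-8, 0.3), ("b", 1e-4, 0.2), ("c", 1e-2, 0.1)])
        _, above = rank_reactivated(cls, "b")
        assert above == 1

    def test_reference_first(self):
        cls = self._classes([("a", 1e-8, 0.3), ("b", 1e-4, 0.2)])
        _, above = rank_reactivated(cls, "a")
        assert above == 0

    def test_tie_broken_by_delta(self):
        cls = self._classes([("a", 0.0, 0.3), ("b", 0.0, 0.2)])
        _, above = rank_reactivated(cls, "b")
        assert above == 1

    def test_reference_not_reactivated_errors(self):
        cls = self._classes([("a", 1e-8, 0.3)])
        cls.loc[0, "status"] = "non_reactivated"
        with pytest.raises(ValueError, match="not reactivated"):
            rank_reactivated(cls, "a")


class TestDeltaProfile:
    def test_arithmetic_and_order(self):
        rows = _gene_rows("g1", [(1, 99)] * 3, [(21, 79)] * 3)
        rows += _gene_rows("g2", [(20, 80)] * 3, [(20, 80)] * 3)
        genes = pd.DataFrame({"gene_id": ["g1", "g2"], "tss": [500, 100]})
        prof = delta_ratio_profile(_table(rows), genes, {"g1", "g2"})
        assert list(prof["gene_id"]) == ["g2", "g1"]  # TSS order
        assert prof.set_index("gene_id").loc["g1", "delta_ratio"] == pytest.approx(0.20)
        assert prof.set_index("gene_id").loc["g2", "delta_ratio"] == pytest.approx(0.0)
        assert prof["delta_ratio"].between(-1, 1).all()


class TestPartitionProperty:
    def test_every_gene_exactly_one_status(self, small_bundle):
        cfg, bundle, truth = small_bundle
        from xreact.classify import load_count_table
        from xreact.core import read_gene_table

        genes = read_gene_table(bundle["genes"])
        table = load_count_table(bundle["counts"])
        classes = classify_genes(table, [g.gene_id for g in genes])
        assert len(classes) == cfg.n_genes
        assert classes["gene_id"].is_unique
        assert set(classes["status"]) <= {
            "uninformative", "escapee", "reactivated", "non_reactivated"
        }
        assert classes["status"].value_counts().sum() == cfg.n_genes
        # delta ratios bounded
        d = classes["delta_ratio"].dropna()
        assert d.between(-1, 1).all()
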