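"""Differential testing, batch combination, adjustment and enrichment."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from glycosecretome.differential_stats import (
    DifferentialRecord,
    batch_fold_change,
    benjamini_hochberg,
    enrich_sets,
    fisher_combine,
    glycoform_differential,
    select_secretory_cluster,
    variance_gated_ttest,
)
from tests.conftest import make_quant_table


def pooled_t_pvalue(a, b):
    """Closed-form pooled two-sample t oracle."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))
    return t, 2 * stats.t.sf(abs(t), na + nb - 2)


class TestGlycoformDifferential:
    def test_worked_example_matches_pooled_t_oracle(self):
        """a=(10,11,12) vs b=(13,14,15) on log values: t=-3.674, p~0.021, down."""
        table = make_quant_table({"f1": [10, 11, 12, 13, 14, 15]},
                                 ["a1", "a2", "a3", "b1", "b2", "b3"])
        (record,) = glycoform_differential(
            table, ["a1", "a2", "a3"], ["b1", "b2", "b3"], log_transform=False)
        t, p = pooled_t_pvalue([10, 11, 12], [13, 14, 15])
        assert t == pytest.approx(-3.674234614, abs=1e-8)
        assert record.p_value == pytest.approx(p, abs=1e-12)
        assert record.p_value == pytest.approx(0.0213, abs=5e-4)
        assert record.log2_fold_change == pytest.approx(-3.0)
        assert record.significant and record.direction == "down"

    def test_identical_groups_not_significant(self):
        table = make_quant_table({"f1": [5, 6, 7, 5, 6, 7]},
                                 ["a1", "a2", "a3", "b1", "b2", "b3"])
        (record,) = glycoform_differential(
            table, ["a1", "a2", "a3"], ["b1", "b2", "b3"], log_transform=False)
        assert record.p_value == pytest.approx(1.0)
        assert not record.significant and record.direction == "none"

    def test_zero_variance_equal_means_p_one(self):
        table = make_quant_table({"f1": [1, 1, 1, 1, 1, 1]},
                                 ["a1", "a2", "a3", "b1", "b2", "b3"])
        (record,) = glycoform_differential(
            table, ["a1", "a2", "a3"], ["b1", "b2", "b3"], log_transform=False)
        assert record.p_value == 1.0

    def test_zero_variance_unequal_means_p_zero(self, caplog):
        table = make_quant_table({"f1": [1, 1, 1, 2, 2, 2]},
                                 ["a1", "a2", "a3", "b1", "b2", "b3"])
        with caplog.at_level("WARNING"):
            (record,) = glycoform_differential(
                table, ["a1", "a2", "a3"], ["b1", "b2", "b3"], log_transform=False)
        assert record.p_value == 0.0
        assert "zero variance" in caplog.text

    def test_short_group_skipped_with_warning(self, caplog):
        table = make_quant_table(
            {"f1": [10, np.nan, np.nan, 13, 14, 15],
             "f2": [10, 11, 12, 13, 14, 15]},
            ["a1", "a2", "a3", "b1", "b2", "b3"])
        with caplog.at_level("WARNING"):
            records = glycoform_differential(
                table, ["a1", "a2", "a3"], ["b1", "b2", "b3"], log_transform=False)
        assert [r.feature for r in records] == ["f2"]
        assert "skipped" in caplog.text

    def test_log2_transform_and_metadata_selectors(self):
        meta = pd.DataFrame(
            {"genotype": ["sTg"] * 3 + ["WT"] * 3,
             "sex": ["F"] * 6, "region": ["cortex"] * 6, "batch": [1, 1, 2] * 2},
            index=pd.Index([f"s{i}" for i in range(6)], name="sample_id"))
        table = make_quant_table({"f1": [4, 4, 4, 1, 1, 1]},
                                 list(meta.index), meta=meta)
        (record,) = glycoform_differential(
            table, {"genotype": "sTg"}, {"genotype": "WT"})
        assert record.log2_fold_change == pytest.approx(2.0)

    def test_label_swap_negates_fold_change(self, rng):
        samples = [f"s{i}" for i in range(6)]
        table = make_quant_table(
            {f"f{k}": rng.lognormal(10, 1, 6) for k in range(20)}, samples)
        fwd = glycoform_differential(table, samples[:3], samples[3:])
        rev = glycoform_differential(table, samples[3:], samples[:3])
        for r_fwd, r_rev in zip(fwd, rev):
            assert r_fwd.p_value == pytest.approx(r_rev.p_value, rel=1e-9)
            assert r_fwd.log2_fold_change == pytest.approx(
                -r_rev.log2_fold_change, rel=1e-9)


class TestVarianceGatedTTest:
    def test_equal_variances_take_pooled_branch(self):
        _, expected = pooled_t_pvalue([10, 11, 12], [13, 14, 15])
        assert variance_gated_ttest([10, 11, 12], [13, 14, 15]) == pytest.approx(
            expected, abs=1e-12)

    def test_unequal_variances_take_welch_branch(self):
        a, b = [0.0, 10.0, 20.0], [19.9, 20.0, 20.1]
        var_ratio = np.var(a, ddof=1) / np.var(b, ddof=1)
        assert var_ratio == pytest.approx(10000.0)
        f_p = 2 * min(stats.f.cdf(var_ratio, 2, 2), stats.f.sf(var_ratio, 2, 2))
        assert f_p < 0.05  # F-distribution oracle: gate must reject
        expected = stats.ttest_ind(a, b, equal_var=False).pvalue
        assert variance_gated_ttest(a, b) == pytest.approx(expected, abs=1e-12)
        assert variance_gated_ttest(a, b) != pytest.approx(
            stats.ttest_ind(a, b, equal_var=True).pvalue, abs=1e-6)

    def test_needs_two_values_per_group(self):
        with pytest.raises(ValueError):
            variance_gated_ttest([1.0], [1.0, 2.0])


class TestFisherCombine:
    def test_worked_example_closed_form(self):
        """fisher(0.05, 0.05): X2=11.983, df 4, p = exp(-x/2)(1+x/2)."""
        x2 = -2 * (math.log(0.05) + math.log(0.05))
        assert x2 == pytest.approx(11.9829, abs=1e-4)
        closed_form = math.exp(-x2 / 2) * (1 + x2 / 2)
        assert fisher_combine([0.05, 0.05]) == pytest.approx(closed_form, abs=1e-12)
        assert fisher_combine([0.05, 0.05]) == pytest.approx(0.01748, abs=1e-5)

    def test_all_ones_combine_to_one(self):
        assert fisher_combine([1.0, 1.0]) == pytest.approx(1.0)

    @settings(max_examples=100, derandomize=True)
    @given(p=st.floats(1e-6, 1.0))
    def test_singleton_is_identity(self, p):
        assert fisher_combine([p]) == pytest.approx(p, rel=1e-9)

    @pytest.mark.parametrize("bad", [[], [0.0, 0.5], [0.5, 1.5]])
    def test_rejects_invalid(self, bad):
        with pytest.raises(ValueError):
            fisher_combine(bad)


def test_batch_fold_change_is_log2_mean():
    assert batch_fold_change(1.0, 1.0) == 1.0
    assert batch_fold_change(0.0, 2.0) == 1.0
    assert batch_fold_change(-1.5, -1.5) == -1.5
    with pytest.raises(ValueError):
        batch_fold_change(np.inf, 1.0)


def bh_reference(pvals):
    """Brute-force step-up BH oracle."""
    p = np.asarray(pvals, float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(n)
    running_min = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, p[i] * n / rank)
        adjusted[i] = running_min
    return np.clip(adjusted, 0, 1)


class TestBenjaminiHochberg:
    def test_worked_example(self):
        np.testing.assert_allclose(
            benjamini_hochberg([0.01, 0.02, 0.03, 0.04]), [0.04] * 4, atol=1e-12)

    def test_singleton_and_ties(self):
        np.testing.assert_allclose(benjamini_hochberg([0.3]), [0.3])
        np.testing.assert_allclose(benjamini_hochberg([0.2] * 5), [0.2] * 5)

    def test_matches_brute_force_reference(self, rng):
        for _ in range(50):
            pvals = rng.uniform(size=rng.integers(1, 40))
            np.testing.assert_allclose(
                benjamini_hochberg(pvals), bh_reference(pvals), atol=1e-12)


class TestEnrichSets:
    def test_worked_hypergeometric_example(self):
        """|bg|=10, set 5, |fg|=4, overlap 4 -> p = 5/210 by enumeration."""
        background = set(range(10))
        annotation = {"s": set(range(5))}
        result = enrich_sets(set(range(4)), background, annotation)
        assert result.loc["s", "overlap"] == 4
        assert result.loc["s", "p"] == pytest.approx(5 / 210, abs=1e-12)

    def test_matches_exhaustive_enumeration(self, rng):
        """p(X >= k) equals enumeration over all foreground draws, |bg| <= 20."""
        from itertools import combinations
        from math import comb

        background = set(range(12))
        members = set(rng.choice(12, size=5, replace=False).tolist())
        foreground = set(rng.choice(12, size=4, replace=False).tolist())
        k = len(foreground & members)
        total = comb(12, 4)
        count = sum(1 for draw in combinations(background, 4)
                    if len(set(draw) & members) >= k)
        result = enrich_sets(foreground, background, {"m": members})
        assert result.loc["m", "p"] == pytest.approx(count / total, abs=1e-12)

    def test_disjoint_foreground_p_one(self):
        result = enrich_sets({0, 1}, set(range(10)), {"s": {8, 9}})
        assert result.loc["s", "p"] <= 1.0
        result0 = enrich_sets({0, 1}, set(range(10)), {"s": set()})
        assert result0.loc["s", "p"] == pytest.approx(1.0)

    def test_foreground_equals_background(self):
        background = set(range(10))
        result = enrich_sets(background, background, {"s": {1, 2, 3}})
        assert result.loc["s", "overlap"] == 3

    def test_empty_background_errors(self):
        with pytest.raises(ValueError):
            enrich_sets(set(), set(), {"s": {1}})


class TestSecretoryCluster:
    @staticmethod
    def _record(feature, significant):
        return DifferentialRecord(feature, 1.0 if significant else 0.0,
                                  0.01 if significant else 0.5,
                                  significant, "up" if significant else "none")

    def test_selection_rule(self):
        diff = {
            "proteome": [self._record("P1", True), self._record("P2", False)],
            "acetyl": [self._record("P3", True), self._record("P4", True)],
        }
        pathways = {"lysosome": {"P1", "P2"}, "other types of N-glycan": {"P3", "P5"}}
        assert select_secretory_cluster(diff, pathways) == {"P1", "P3"}

    def test_tuple_features_use_protein_component(self):
        diff = {"glyco": [self._record(("P9", 42, "HexNAc(2)Hex(9)"), True)]}
        assert select_secretory_cluster(diff, {"p": {"P9"}}) == {"P9"}
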