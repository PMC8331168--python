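"""Group tests, compact letter displays and qPCR NRQ normalization."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from prmkit.errors import ConfigurationError
from prmkit.stats import (
    anova_tukey_letters, kruskal_lsd_letters, nrq, summarize_groups,
    two_group_test,
)


class TestTwoGroupTest:
    def test_identical_groups(self):
        res = two_group_test([1, 2, 3], [1, 2, 3])
        assert res.t == 0.0 and res.p == 1.0 and not res.significant

    def test_clear_separation(self):
        res = two_group_test([0.9, 1.0, 1.1], [1.9, 2.0, 2.1])
        assert abs(res.t) == pytest.approx(12.2474, abs=1e-3)
        assert res.p < 0.001 and res.significant

    def test_matches_scipy_pooled_t(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            a, b = rng.normal(size=(2, 4))
            res = two_group_test(a, b)
            t, p = sps.ttest_ind(a, b, equal_var=True)
            assert res.t == pytest.approx(t, rel=1e-12)
            assert res.p == pytest.approx(p, rel=1e-12)

    def test_zero_variance_conventions(self):
        equal = two_group_test([2.0, 2.0], [2.0, 2.0])
        assert equal.p == 1.0 and not equal.significant
        unequal = two_group_test([2.0, 2.0], [3.0, 3.0])
        assert unequal.p == 0.0 and unequal.significant
        assert unequal.warning is not None

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            two_group_test([1.0], [1.0, 2.0])


def assert_biconditional(display):
    for (g1, g2), p in display.pairwise_p.items():
        share = bool(set(display.letters[g1]) & set(display.letters[g2]))
        assert share == (p >= display.alpha), (g1, g2, p, display.letters)


class TestLetterDisplays:
    def test_identical_groups_share_single_letter(self):
        rng = np.random.default_rng(1)
        groups = {g: list(rng.normal(0, 1, 4)) for g in "abcd"}
        # same values for every group
        vals = groups["a"]
        groups = {g: vals for g in "abcd"}
        disp = anova_tukey_letters(groups)
        assert all(lett == "a" for lett in disp.letters.values())
        assert_biconditional(disp)

    def test_shifted_group_gets_unique_letter(self):
        rng = np.random.default_rng(2)
        groups = {
            "wt": list(rng.normal(1.0, 0.05, 3)),
            "ox": list(rng.normal(1.05, 0.05, 3)),
            "s91d": list(rng.normal(10.0, 0.05, 3)),
        }
        disp = anova_tukey_letters(groups)
        unique = set(disp.letters["s91d"])
        assert not (unique & set(disp.letters["wt"]))
        assert not (unique & set(disp.letters["ox"]))
        assert_biconditional(disp)

    @pytest.mark.parametrize("n_groups", [3, 4, 5, 6])
    def test_tukey_letters_consistent_on_random_data(self, n_groups):
        rng = np.random.default_rng(n_groups)
        for _ in range(10):
            shifts = rng.uniform(0, 3, size=n_groups)
            groups = {
                f"g{i}": list(rng.normal(shifts[i], 0.5, 3)) for i in range(n_groups)
            }
            disp = anova_tukey_letters(groups)
            assert_biconditional(disp)

    def test_kruskal_identical_groups_single_letter(self):
        groups = {g: [1.0, 2.0, 3.0, 4.0] for g in "abc"}
        disp = kruskal_lsd_letters(groups)
        assert set(disp.letters.values()) == {"a"}

    def test_kruskal_dominant_group_distinct_letter(self):
        rng = np.random.default_rng(3)
        groups = {
            "a": list(rng.uniform(0, 1, 5)),
            "b": list(rng.uniform(0, 1, 5)),
            "c": list(rng.uniform(100, 101, 5)),
        }
        disp = kruskal_lsd_letters(groups)
        assert not (set(disp.letters["c"]) & set(disp.letters["a"]))
        assert_biconditional(disp)

    def test_kruskal_bonferroni_factor_is_pair_count(self):
        # with k groups the smallest achievable adjusted p is raw * C(k,2)
        rng = np.random.default_rng(4)
        groups = {f"g{i}": list(rng.normal(i * 5, 0.1, 4)) for i in range(4)}
        disp = kruskal_lsd_letters(groups)
        assert len(disp.pairwise_p) == 6
        assert_biconditional(disp)

    def test_group_with_single_value_rejected(self):
        with pytest.raises(ValueError):
            anova_tukey_letters({"a": [1.0], "b": [1.0, 2.0]})

    def test_summary_table_columns(self):
        groups = {"a": [1.0, 1.1, 0.9], "b": [2.0, 2.1, 1.9]}
        disp = anova_tukey_letters(groups)
        out = summarize_groups(groups, disp)
        assert list(out.columns) == ["group", "mean", "sd", "n", "letters"]
        assert out.loc[out.group == "a", "n"].item() == 3


def cq_frame(entries):
    return pd.DataFrame(entries, columns=["gene", "sample", "cq"])


class TestNrq:
    def make_table(self, target_shift=None, sample_shift=None):
        genes = ["UBC", "UBQ10", "TARGET"]
        samples = ["s1", "s2", "s3"]
        rows = []
        for g in genes:
            for s in samples:
                cq = 20.0
                if target_shift and g == "TARGET" and s == target_shift[0]:
                    cq += target_shift[1]
                if sample_shift and s == sample_shift[0]:
                    cq += sample_shift[1]
                for _ in range(2):  # technical duplicates
                    rows.append((g, s, cq))
        return cq_frame(rows)

    def test_all_equal_cq_gives_unit_nrq(self):
        out = nrq(self.make_table(), {g: 2.0 for g in ["UBC", "UBQ10", "TARGET"]},
                  ["UBC", "UBQ10"])
        assert np.allclose(out["nrq"], 1.0)

    def test_one_cycle_lower_doubles_nrq(self):
        out = nrq(self.make_table(target_shift=("s1", -1.0)),
                  {g: 2.0 for g in ["UBC", "UBQ10", "TARGET"]}, ["UBC", "UBQ10"])
        t = out[out.gene == "TARGET"].set_index("sample")["nrq"]
        assert t["s1"] / t["s2"] == pytest.approx(2.0, rel=1e-12)

    def test_uniform_per_sample_shift_cancels(self):
        base = nrq(self.make_table(target_shift=("s1", -0.7)),
                   {g: 2.0 for g in ["UBC", "UBQ10", "TARGET"]}, ["UBC", "UBQ10"])
        shifted = nrq(self.make_table(target_shift=("s1", -0.7), sample_shift=("s2", 1.3)),
                      {g: 2.0 for g in ["UBC", "UBQ10", "TARGET"]}, ["UBC", "UBQ10"])
        a = base.set_index(["gene", "sample"])["nrq"]
        b = shifted.set_index(["gene", "sample"])["nrq"]
        assert np.allclose(a, b, atol=1e-9)

    def test_technical_replicate_sd_propagates_to_se(self):
        rows = []
        for g in ["UBC", "UBQ10", "TARGET"]:
            for s in ["s1", "s2"]:
                noisy = g == "TARGET" and s == "s1"
                for d in ([-0.2, 0.2] if noisy else [0.0, 0.0]):
                    rows.append((g, s, 20.0 + d))
        out = nrq(cq_frame(rows), {g: 2.0 for g in ["UBC", "UBQ10", "TARGET"]},
                  ["UBC", "UBQ10"])
        se = out.set_index(["gene", "sample"])["se"]
        assert se["TARGET", "s1"] > se["TARGET", "s2"]
        # delta method: se = nrq * ln(E) * sd(mean Cq)
        sd_mean = np.std([-0.2, 0.2], ddof=1) / np.sqrt(2)
        assert se["TARGET", "s1"] == pytest.approx(
            float(out.set_index(["gene", "sample"])["nrq"]["TARGET", "s1"])
            * np.log(2.0) * sd_mean, rel=1e-9
        )

    def test_missing_reference_cq_names_sample(self):
        table = self.make_table()
        table = table[~((table.gene == "UBC") & (table["sample"] == "s2"))]
        with pytest.raises(ConfigurationError, match="s2"):
            nrq(table, {g: 2.0 for g in ["UBC", "UBQ10", "TARGET"]}, ["UBC", "UBQ10"])

    def test_requires_two_reference_genes(self):
        with pytest.raises(ConfigurationError):
            nrq(self.make_table(), {"UBC": 2.0}, ["UBC"])
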