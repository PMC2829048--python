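import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lgtscreen.copy_number import (
    anova_tukey,
    copy_number_call,
    fold_change,
    summarize_ratios,
)


def _table(values_by_locus, strain="S1"):
    rows = []
    for locus, vals in values_by_locus.items():
        for i, v in enumerate(vals):
            rows.append((locus, strain, i + 1, v))
    return pd.DataFrame(rows, columns=["locus", "strain", "replicate", "ratio"])


class TestSummaries:
    def test_constant_ratios(self):
        out = summarize_ratios(_table({"g": [1, 1, 1]}))
        pooled = out[out.strain == "pooled"].iloc[0]
        assert pooled["mean"] == 1.0 and pooled["se"] == 0.0

    def test_hand_arithmetic(self):
        out = summarize_ratios(_table({"g": [0.9, 1.1]}))
        pooled = out[out.strain == "pooled"].iloc[0]
        assert pooled["mean"] == pytest.approx(1.0)
        assert pooled["se"] == pytest.approx(0.1)

    def test_single_replicate_flagged(self):
        out = summarize_ratios(_table({"g": [1.2]}))
        assert out.iloc[0]["single_replicate"]

    def test_positive_ratio_required(self):
        with pytest.raises(ValueError):
            summarize_ratios(_table({"g": [1.0, -0.5]}))


class TestAnovaTukey:
    def test_degenerate_constant_groups(self):
        r = anova_tukey({"a": np.ones(3), "b": np.ones(3)})
        assert r.f_stat == 0.0 and r.p == 1.0
        assert (r.pairwise["p_adj"] == 1.0).all()

    def test_extreme_separation_flagged(self, rng):
        a = 1.0 + rng.normal(0, 1e-4, size=5)
        b = 2.0 + rng.normal(0, 1e-4, size=5)
        r = anova_tukey({"a": a, "b": b})
        assert r.p < 1e-6
        assert (r.pairwise["p_adj"] < 0.001).all()

    def test_tukey_at_least_as_conservative_as_t(self, rng):
        # adjusted pairwise p >= unadjusted two-sample t p, on random draws
        for _ in range(10):
            groups = {k: rng.normal(0, 1, size=6) for k in "abcd"}
            r = anova_tukey(groups)
            for g1, g2, _, p_adj in r.pairwise.itertuples(index=False):
                p_t = stats.ttest_ind(groups[g1], groups[g2]).pvalue
                assert p_adj >= p_t - 1e-9

    def test_type_one_error_calibration(self, rng):
        # omnibus F at alpha=0.05 under the null
        rejections = 0
        n_sims = 800
        for _ in range(n_sims):
            groups = {k: rng.normal(0, 1, size=10) for k in "abc"}
            if anova_tukey(groups, compute_pairwise=False).p < 0.05:
                rejections += 1
        assert 0.03 <= rejections / n_sims <= 0.07

    def test_single_observation_group_rejected(self):
        with pytest.raises(ValueError):
            anova_tukey({"a": np.ones(1), "b": np.ones(3)})


class TestCopyNumberCall:
    def _sim_table(self, seed, kind):
        from lgtscreen import synthetic_data as sd

        cfg = sd.GeneratorConfig(seed=seed)
        rng = np.random.default_rng(seed)
        if kind == "genomic":
            return sd.simulate_qpcr(["locus"], [], cfg, rng)
        return sd.simulate_qpcr([], ["locus"], cfg, rng)

    def test_genomic_locus_called_single_copy(self):
        hits = sum(
            copy_number_call(self._sim_table(s, "genomic"))[0].call == "single_copy_genomic"
            for s in range(40))
        assert hits >= 34

    def test_contaminant_locus_called_variable(self):
        hits = sum(
            copy_number_call(self._sim_table(s, "contaminant"))[0].call == "variable_titer"
            for s in range(40))
        assert hits >= 38

    def test_degenerate_exact_ones(self):
        t = _table({"g": [1.0, 1.0]})
        assert copy_number_call(t)[0].call == "single_copy_genomic"

    def test_scale_invariance_through_ratios(self):
        # the verdict depends on ratios only: scaling target and standard
        # copies together leaves the table, hence the verdict, unchanged
        t = self._sim_table(3, "genomic")
        v1 = copy_number_call(t)[0]
        t2 = t.copy()
        t2["ratio"] = (t2["ratio"] * 7.3) / 7.3
        v2 = copy_number_call(t2)[0]
        assert v1.call == v2.call and v1.mean_ratio == pytest.approx(v2.mean_ratio)

    def test_mean_outside_band_is_variable(self):
        t = _table({"g": [3.0, 3.1, 2.9, 3.0]})
        assert copy_number_call(t)[0].call == "variable_titer"


class TestFoldChange:
    def _expr(self, folds):
        rows = []
        for tissue, mean in folds.items():
            for rep in range(4):
                rows.append(("locus", tissue, rep + 1, mean * (1 + 0.01 * rep)))
        return pd.DataFrame(rows, columns=["locus", "tissue", "replicate", "copies"])

    def test_reference_fold_is_one_equivalent(self):
        out = fold_change(self._expr({"whole_body": 2.0, "bacteriocyte": 2.0}))
        row = out[out.tissue == "bacteriocyte"].iloc[0]
        assert row["fold"] == pytest.approx(1.0)

    def test_constructed_fold(self):
        out = fold_change(self._expr({"whole_body": 1.0, "bacteriocyte": 11.6}))
        row = out[out.tissue == "bacteriocyte"].iloc[0]
        assert row["fold"] == pytest.approx(11.6)
        assert row["p_adj"] < 0.001

    def test_missing_reference_flagged(self):
        out = fold_change(self._expr({"bacteriocyte": 5.0}))
        assert out.iloc[0]["missing_reference"]
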