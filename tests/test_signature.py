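"""Differential expression, P3-like detection and WKS enrichment."""

import numpy as np
import pandas as pd
import pytest

from allprog import signature
from allprog.classify import SignatureGenes


def _assignments(groups):
    return pd.DataFrame(
        {"group": groups, "klass": [g if g == "P3" else "P1" for g in groups]},
        index=pd.Index([f"s{i}" for i in range(len(groups))], name="sample_id"),
    )


def _matrix(rows, samples):
    return pd.DataFrame(
        rows, index=[f"g{i}" for i in range(len(rows))], columns=samples
    )


class TestDifferentialExpression:
    def test_separated_groups_match_exact_enumeration(self):
        # 4 vs 4 completely separated ranks: the exact two-sided
        # Mann-Whitney p is 2 / C(8,4) = 2/70 (both extreme orderings)
        assign = _assignments(["P3"] * 4 + ["P1&2"] * 4)
        matrix = _matrix([[1, 2, 3, 4, 10, 11, 12, 13]], assign.index)
        res = signature.differential_expression(matrix, assign, adjust=None)
        assert np.isclose(res["p_raw"].iloc[0], 2 / 70)
        assert res["direction"].iloc[0] == "down_in_P3"

    def test_label_swap_flips_direction_keeps_p(self):
        rng = np.random.default_rng(0)
        assign = _assignments(["P3"] * 6 + ["P1&2"] * 6)
        flipped = assign.assign(group=np.where(assign["group"] == "P3", "P1&2", "P3"))
        matrix = _matrix(rng.normal(0, 1, (20, 12)), assign.index)
        matrix.iloc[:5, :6] += 2.0
        a = signature.differential_expression(matrix, assign)
        b = signature.differential_expression(matrix, flipped)
        assert np.allclose(a["p_raw"], b["p_raw"])
        assert (
            a["direction"].map({"up_in_P3": "down_in_P3", "down_in_P3": "up_in_P3"})
            == b["direction"]
        ).all()

    def test_adjusted_p_dominates_raw_and_is_monotone(self):
        rng = np.random.default_rng(1)
        assign = _assignments(["P3"] * 5 + ["P1&2"] * 5)
        matrix = _matrix(rng.normal(0, 1, (50, 10)), assign.index)
        res = signature.differential_expression(matrix, assign)
        assert (res["p_adjusted"] >= res["p_raw"] - 1e-12).all()
        by_raw = res.sort_values("p_raw")
        assert by_raw["p_adjusted"].is_monotonic_increasing

    def test_constant_gene_never_significant(self):
        assign = _assignments(["P3"] * 4 + ["P1&2"] * 4)
        matrix = _matrix([[3.0] * 8, [1, 2, 3, 4, 5, 6, 7, 8]], assign.index)
        res = signature.differential_expression(matrix, assign)
        assert res["p_raw"].iloc[0] == 1.0 and not res["significant"].iloc[0]

    def test_recovers_planted_shift(self):
        # 100 shifted genes among 400, shift = 2 noise SD, 60 per group
        rng = np.random.default_rng(2)
        assign = _assignments(["P3"] * 60 + ["P1&2"] * 60)
        sd = 0.5
        matrix = _matrix(rng.normal(5, sd, (400, 120)), assign.index)
        matrix.iloc[:100, :60] += 2 * sd
        res = signature.differential_expression(matrix, assign)
        planted = res.iloc[:100]
        sensitivity = (planted["significant"] & (planted["direction"] == "up_in_P3")).mean()
        assert sensitivity >= 0.9
        fp = res.iloc[100:]["significant"].mean()
        assert fp < 0.05

    def test_requires_three_samples_per_group(self):
        assign = _assignments(["P3"] * 2 + ["P1&2"] * 6)
        matrix = _matrix([[1.0] * 8], assign.index)
        with pytest.raises(ValueError, match=">= 3"):
            signature.differential_expression(matrix, assign)


class TestP3Like:
    def _setup(self):
        rng = np.random.default_rng(3)
        assign = _assignments(["P3"] * 10 + ["P1&2"] * 10)
        baselines = rng.normal(5, 1.5, 30)
        matrix = _matrix(
            baselines[:, None] + rng.normal(0, 0.3, (30, 20)), assign.index
        )
        matrix.iloc[:8, :10] += 2.0  # up in P3
        matrix.iloc[8:15, :10] -= 2.0  # down in P3
        return matrix, assign

    def test_exact_copy_of_p3_centroid_is_flagged(self):
        matrix, assign = self._setup()
        genes = list(matrix.index[:15])
        p3_cols = assign.index[assign["group"] == "P3"]
        matrix.loc[genes, "s10"] = matrix.loc[genes, p3_cols].mean(axis=1)
        flagged = signature.detect_p3_like(matrix, assign, genes)
        assert "s10" in flagged

    def test_equidistant_sample_not_flagged(self):
        assign = _assignments(["P3"] * 3 + ["P1&2"] * 3)
        # both centroids identical: correlations tie, strict rule says no flag
        matrix = _matrix(np.tile([[1.0], [2.0], [4.0]], 6), assign.index)
        flagged = signature.detect_p3_like(matrix, assign, list(matrix.index))
        assert flagged == []

    def test_p3_model_samples_mostly_flagged(self):
        matrix, assign = self._setup()
        genes = list(matrix.index[:15])
        rng = np.random.default_rng(4)
        p12_cols = list(assign.index[assign["group"] == "P1&2"])[:3]
        # regenerate three good-prognosis samples from the P3 expression model
        p3_cols = list(assign.index[assign["group"] == "P3"])
        p3_mean = matrix.loc[genes, p3_cols].mean(axis=1)
        matrix.loc[genes, p12_cols] = (
            p3_mean.to_numpy()[:, None] + rng.normal(0, 0.3, (len(genes), 3))
        )
        flagged = signature.detect_p3_like(matrix, assign, genes)
        assert set(p12_cols) <= set(flagged)
        clean = set(assign.index[assign["group"] == "P1&2"]) - set(p12_cols)
        assert len(set(flagged) & clean) <= 1

    def test_empty_signature_rejected(self):
        matrix, assign = self._setup()
        with pytest.raises(ValueError, match="empty"):
            signature.detect_p3_like(matrix, assign, [])


class TestWKS:
    def _ranked(self, n=500, seed=0):
        rng = np.random.default_rng(seed)
        w = np.sort(rng.normal(0, 1, n))[::-1]
        return pd.Series(w, index=[f"g{i}" for i in range(n)])

    def test_whole_universe_scores_zero_with_p_one(self):
        ranked = self._ranked()
        res = signature.wks_enrichment(ranked, {"all": list(ranked.index)}, n_perm=99)
        assert res.loc["all", "enrichment_score"] == pytest.approx(0.0, abs=1e-9)
        assert res.loc["all", "p_value"] == 1.0

    def test_top_ranked_set_attains_permutation_minimum(self):
        ranked = self._ranked(n=2000)
        top = [f"g{i}" for i in range(50)]
        res = signature.wks_enrichment(ranked, {"top": top}, n_perm=199, seed=5)
        assert res.loc["top", "p_value"] == pytest.approx(1 / 200)
        assert res.loc["top", "direction"] == "up"

    def test_p_values_invariant_to_weight_rescaling(self):
        ranked = self._ranked(n=300, seed=6)
        sets = {"a": [f"g{i}" for i in range(40, 80)], "b": [f"g{i}" for i in range(0, 300, 7)]}
        res1 = signature.wks_enrichment(ranked, sets, n_perm=99, seed=7)
        res2 = signature.wks_enrichment(ranked * 13.7, sets, n_perm=99, seed=7)
        assert np.allclose(res1["p_value"], res2["p_value"])

    def test_same_seed_reproduces_p_values(self):
        ranked = self._ranked(n=300, seed=8)
        sets = {"a": [f"g{i}" for i in range(30)]}
        a = signature.wks_enrichment(ranked, sets, n_perm=99, seed=9)
        b = signature.wks_enrichment(ranked, sets, n_perm=99, seed=9)
        assert a.equals(b)

    def test_small_sets_skipped_with_warning(self):
        ranked = self._ranked()
        with pytest.warns(UserWarning, match="skipped"):
            res = signature.wks_enrichment(ranked, {"tiny": ["g1", "g2"]}, n_perm=99)
        assert res.empty


def test_ranked_list_is_fold_change_sorted_permutation():
    de = pd.DataFrame(
        {"fold_change": [0.5, -1.0, 2.0]}, index=["a", "b", "c"]
    )
    ranked = signature.make_ranked_list(de)
    assert list(ranked.index) == ["c", "a", "b"]
    assert set(ranked.index) == set(de.index)
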