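"""RT-qPCR arm: QC gates, the ratio formula, thresholds, classification."""

import itertools

import numpy as np
import pandas as pd
import pytest

from allprog import classify, qpcr
from allprog.classify import SignatureGenes
from allprog.simulate import (
    CONTROL_GENES,
    FREQUENT_GENES,
    NEGATIVE_GENES,
    POSITIVE_GENES,
    SimConfig,
    simulate_ct_table,
)

SIG = SignatureGenes(positive=list(POSITIVE_GENES), negative=list(NEGATIVE_GENES))


def _record(sample, gene, ct, no_rt=38.0, spread=0.2, role="prognostic"):
    return {
        "sample_id": sample,
        "gene_id": gene,
        "ct_dup1": ct + spread / 2,
        "ct_dup2": ct - spread / 2,
        "ct_noRT": no_rt,
        "role": role,
    }


def _table(sample_cts: dict, testis_cts: dict, **kw):
    """Build a Ct table for one sample plus the testis reference."""
    rows = []
    for g, ct in testis_cts.items():
        role = "control" if g in CONTROL_GENES else "prognostic"
        rows.append(_record("testis", g, ct, role=role))
    for g, ct in sample_cts.items():
        role = "control" if g in CONTROL_GENES else "prognostic"
        rows.append(_record("sampleA", g, ct, role=role, **kw))
    return pd.DataFrame(rows)


class TestQC:
    def test_no_rt_boundary_is_inclusive_at_36(self):
        rec = qpcr.qc_ct(pd.DataFrame([_record("s", "g", 25.0, no_rt=36.0)]))
        assert rec["qc_flags"].iloc[0] == []
        rec = qpcr.qc_ct(pd.DataFrame([_record("s", "g", 25.0, no_rt=35.99)]))
        assert rec["qc_flags"].iloc[0] == ["NO_RT_CONTAMINATION"]

    def test_duplicate_spread_boundary_at_half_cycle(self):
        ok = qpcr.qc_ct(pd.DataFrame([_record("s", "g", 30.2, spread=0.4)]))
        assert ok["qc_pass"].iloc[0]
        bad = qpcr.qc_ct(
            pd.DataFrame(
                [{"sample_id": "s", "gene_id": "g", "ct_dup1": 30.0, "ct_dup2": 30.6,
                  "ct_noRT": 38.0, "role": "prognostic"}]
            )
        )
        assert bad["qc_flags"].iloc[0] == ["DUPLICATE_SPREAD"]
        exactly_half = qpcr.qc_ct(pd.DataFrame([_record("s", "g", 30.0, spread=0.5)]))
        assert "DUPLICATE_SPREAD" in exactly_half["qc_flags"].iloc[0]

    def test_unstable_control_gene_flagged_by_cv(self):
        rows = [
            _record(f"s{i}", "ACTB", ct, role="control")
            for i, ct in enumerate([20.0, 30.0, 20.0, 30.0])
        ]
        rec = qpcr.qc_ct(pd.DataFrame(rows))
        assert all("CONTROL_UNSTABLE" in f for f in rec["qc_flags"])

    def test_clean_synthetic_table_has_no_flags(self):
        records, _ = simulate_ct_table(SimConfig(seed=2), n_patients=6)
        rec = qpcr.qc_ct(records)
        assert rec["qc_pass"].all()


class TestRelativeExpression:
    def _cts(self, gene_ct_sample, gene_ct_testis=25.0, ctrl_shift=0.0):
        testis = {"GOI": gene_ct_testis, **{g: 22.0 for g in CONTROL_GENES}}
        sample = {"GOI": gene_ct_sample, **{g: 22.0 + ctrl_shift for g in CONTROL_GENES}}
        return qpcr.qc_ct(_table(sample, testis))

    def test_identical_cts_give_ratio_one(self):
        expr = qpcr.relative_expression(self._cts(25.0))
        assert expr.loc[expr.gene_id == "GOI", "ratio"].iloc[0] == pytest.approx(1.0)

    def test_sign_convention_testis_lower_means_ratio_below_one(self):
        # gene Ct one cycle lower in testis than in the sample: the sample
        # holds half the template, so the printed formula gives 0.5
        expr = qpcr.relative_expression(self._cts(26.0, gene_ct_testis=25.0))
        assert expr.loc[expr.gene_id == "GOI", "ratio"].iloc[0] == pytest.approx(0.5)

    def test_common_shift_of_sample_cancels(self):
        # adding a constant to every Ct of the sample (gene and controls)
        # models a global loading difference: the ratio is unchanged
        a = qpcr.relative_expression(self._cts(25.0))
        b = qpcr.relative_expression(self._cts(25.0 + 1.7, ctrl_shift=1.7))
        assert a.loc[a.gene_id == "GOI", "ratio"].iloc[0] == pytest.approx(
            b.loc[b.gene_id == "GOI", "ratio"].iloc[0]
        )

    def test_round_trip_recovers_planted_ratios_exactly(self):
        cfg = SimConfig(seed=5)
        planted = pd.DataFrame(
            1.0,
            index=pd.Index(["testis", "patient_00"], name="sample_id"),
            columns=list(POSITIVE_GENES + NEGATIVE_GENES + FREQUENT_GENES + CONTROL_GENES),
        )
        planted.loc["patient_00", ["CAMSAP1", "PCGF6", "SH3RF3", "AK022211"]] = [0.5, 1, 2, 8]
        records, _ = simulate_ct_table(cfg, planted_ratios=planted)
        expr = qpcr.relative_expression(qpcr.qc_ct(records))
        got = expr[expr.sample_id == "patient_00"].set_index("gene_id")["ratio"]
        for gene, want in [("CAMSAP1", 0.5), ("PCGF6", 1.0), ("SH3RF3", 2.0), ("AK022211", 8.0)]:
            assert got[gene] == pytest.approx(want, rel=1e-9)

    def test_missing_control_gene_is_named(self):
        testis = {"GOI": 25.0, **{g: 22.0 for g in CONTROL_GENES}}
        sample = {"GOI": 25.0, **{g: 22.0 for g in CONTROL_GENES[:3]}}
        rec = qpcr.qc_ct(_table(sample, testis))
        with pytest.raises(ValueError, match=CONTROL_GENES[3]):
            qpcr.relative_expression(rec)

    def test_failed_qc_gives_nan_ratio(self):
        rec = self._cts(25.0)
        rec.loc[rec.gene_id == "GOI", "qc_pass"] = False
        expr = qpcr.relative_expression(rec)
        row = expr[(expr.sample_id == "sampleA") & (expr.gene_id == "GOI")]
        assert not row["qc_pass"].iloc[0] and np.isnan(row["ratio"].iloc[0])


class TestThresholds:
    def _expr(self, ratios, gene="GOI"):
        return pd.DataFrame(
            {
                "sample_id": [f"n{i}" for i in range(len(ratios))],
                "gene_id": gene,
                "ratio": ratios,
                "qc_pass": True,
            }
        )

    def test_all_zero_normals_give_zero_threshold(self):
        thr = qpcr.qpcr_thresholds(self._expr([0.0] * 10))
        assert thr["GOI"] == 0.0

    def test_constant_normals_give_threshold_at_mean(self):
        thr = qpcr.qpcr_thresholds(self._expr([1.0, 1.0, 1.0, 1.0]))
        assert thr["GOI"] == pytest.approx(1.0)

    def test_mean_plus_two_sd_closed_form(self):
        vals = [0.1, 0.2, 0.3, 0.4]
        thr = qpcr.qpcr_thresholds(self._expr(vals))
        assert thr["GOI"] == pytest.approx(np.mean(vals) + 2 * np.std(vals, ddof=1))

    def test_single_normal_rejected(self):
        with pytest.raises(ValueError, match="normal"):
            qpcr.qpcr_thresholds(self._expr([0.5]))


class TestClassifyQpcr:
    def _expr_for_pattern(self, bits):
        genes = SIG.all_genes + list(FREQUENT_GENES)
        rows = []
        for g, on in zip(SIG.all_genes, bits):
            rows.append({"sample_id": "p", "gene_id": g, "ratio": 2.0 if on else 0.001,
                         "qc_pass": True, "qc_flags": []})
        for g in FREQUENT_GENES:
            rows.append({"sample_id": "p", "gene_id": g, "ratio": 0.001,
                         "qc_pass": True, "qc_flags": []})
        return pd.DataFrame(rows), pd.Series(0.05, index=genes)

    def test_matches_array_classifier_on_all_64_patterns(self):
        for bits in itertools.product([False, True], repeat=6):
            expr, thr = self._expr_for_pattern(bits)
            got = qpcr.classify_qpcr(expr, thr, SIG)
            want = classify.classify_counts(sum(bits[:3]), sum(bits[3:]))
            assert got.loc["p", "klass"] == want, bits

    def test_low_confidence_note_when_nothing_detected(self):
        expr, thr = self._expr_for_pattern([False] * 6)
        got = qpcr.classify_qpcr(expr, thr, SIG)
        assert got.loc["p", "klass"] == "P2"
        assert got.loc["p", "quality_note"] == "LOW_CONFIDENCE"

    def test_frequent_gene_detection_rescues_quality(self):
        expr, thr = self._expr_for_pattern([False] * 6)
        expr.loc[expr.gene_id == FREQUENT_GENES[0], "ratio"] = 2.0
        got = qpcr.classify_qpcr(expr, thr, SIG)
        assert got.loc["p", "quality_note"] == "OK"

    def test_qc_failed_sample_reported_separately(self):
        expr, thr = self._expr_for_pattern([True] * 6)
        expr.loc[expr.gene_id == SIG.positive[0], "qc_pass"] = False
        got = qpcr.classify_qpcr(expr, thr, SIG)
        assert got.loc["p", "klass"] == "QC_FAIL"

    def test_contamination_plant_fires_no_rt_gate(self):
        records, _ = simulate_ct_table(
            SimConfig(seed=6), n_patients=3, contaminated=(("patient_01", "CAMSAP1"),)
        )
        rec = qpcr.qc_ct(records)
        bad = rec[(rec.sample_id == "patient_01") & (rec.gene_id == "CAMSAP1")]
        assert bad["ct_noRT"].iloc[0] < 36
        assert "NO_RT_CONTAMINATION" in bad["qc_flags"].iloc[0]

    def test_end_to_end_classification_matches_planted_truth(self):
        cfg = SimConfig(seed=9)
        records, truth = simulate_ct_table(cfg, n_patients=12)
        expr = qpcr.relative_expression(qpcr.qc_ct(records))
        normals = truth["normals"]
        thr = qpcr.qpcr_thresholds(expr[expr.sample_id.isin(normals)])
        assign = qpcr.classify_qpcr(expr[expr.sample_id.isin(truth["patients"])], thr, SIG)
        planted_calls = (
            truth["ratios"].T.loc[SIG.all_genes, truth["patients"]].gt(thr[SIG.all_genes], axis=0)
        )
        want = classify.assign_prognosis(planted_calls, SIG)
        got = assign.loc[want.index, ["npos", "nneg", "klass"]]
        pd.testing.assert_frame_equal(got, want[["npos", "nneg", "klass"]])
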