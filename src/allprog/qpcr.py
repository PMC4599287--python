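"""RT-qPCR arm: Ct QC, testis-relative expression ratios, aberrancy
thresholds and six-gene classification of prospective patients.

Each gene/sample is measured in duplicate with a no-RT control.  QC gates:

* ``NO_RT_CONTAMINATION`` — no-RT Ct < 36 (genomic DNA carry-over);
* ``DUPLICATE_SPREAD`` — duplicate Cts >= 0.5 apart;
* ``CONTROL_UNSTABLE`` — a control gene's Ct coefficient of variation
  across samples exceeds 10%.

Expression relative to a testis reference, normalized to the mean of four
control genes (Actin, U6, RELA, AUP1), follows the published formula::

    ratio = 2^(Ct_gene,testis - Ct_gene,sample)
            / 2^(meanCt_controls,testis - meanCt_controls,sample)

using the duplicate-mean Ct everywhere.  A gene is aberrantly expressed
when its ratio exceeds the mean + 2 SD of ten normal samples (seven bone
marrows, three cord bloods); the boolean pattern of the six prognostic
genes then feeds the unchanged P1/P2/P3 classifier.  Three "frequent"
genes (often aberrantly active in ALL but prognosis-neutral) serve as a
sample-quality check when no prognostic gene is detected.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import classify as _classify
from .classify import SignatureGenes
from .simulate import CONTROL_GENES, FREQUENT_GENES

NO_RT_MIN_CT = 36.0
DUPLICATE_MAX_SPREAD = 0.5
CONTROL_CV_MAX = 0.10


def qc_ct(records: pd.DataFrame) -> pd.DataFrame:
    """Attach advisory QC flags to a Ct record table.

    ``records`` needs columns ``sample_id``, ``gene_id``, ``ct_dup1``,
    ``ct_dup2``, ``ct_noRT`` and ``role`` (control / frequent /
    prognostic).  Adds ``ct_mean``, ``qc_flags`` (list) and ``qc_pass``.
    """
    out = records.copy()
    out["ct_mean"] = (out["ct_dup1"] + out["ct_dup2"]) / 2.0
    flags = [[] for _ in range(len(out))]
    no_rt = out["ct_noRT"].to_numpy() < NO_RT_MIN_CT
    spread = (out["ct_dup1"] - out["ct_dup2"]).abs().to_numpy() >= DUPLICATE_MAX_SPREAD
    controls = out[out["role"] == "control"]
    unstable_controls = set()
    for gene, sub in controls.groupby("gene_id"):
        cts = sub["ct_mean"]
        if len(cts) >= 2 and cts.mean() != 0:
            cv = cts.std(ddof=1) / abs(cts.mean())
            if cv > CONTROL_CV_MAX:
                unstable_controls.add(gene)
    genes = out["gene_id"].to_numpy()
    for i in range(len(out)):
        if no_rt[i]:
            flags[i].append("NO_RT_CONTAMINATION")
        if spread[i]:
            flags[i].append("DUPLICATE_SPREAD")
        if genes[i] in unstable_controls:
            flags[i].append("CONTROL_UNSTABLE")
    out["qc_flags"] = flags
    out["qc_pass"] = [not f for f in flags]
    return out


def relative_expression(
    records: pd.DataFrame,
    testis_sample: str = "testis",
    control_genes: tuple = CONTROL_GENES,
) -> pd.DataFrame:
    """Testis-relative expression ratios for every non-control gene.

    ``records`` must already carry QC columns (see :func:`qc_ct`); records
    failing QC yield ``qc_pass=False`` rows with NaN ratios.  Raises when a
    control gene is missing in a sample or in the testis reference.

    Returns a DataFrame with ``sample_id``, ``gene_id``, ``ratio``,
    ``qc_pass`` and ``qc_flags``.
    """
    if "ct_mean" not in records:
        records = qc_ct(records)
    ct = records.pivot(index="gene_id", columns="sample_id", values="ct_mean")
    if testis_sample not in ct.columns:
        raise ValueError(f"testis reference sample {testis_sample!r} missing")
    for g in control_genes:
        if g not in ct.index:
            raise ValueError(f"control gene {g!r} not measured")
    missing_ctrl = ct.loc[list(control_genes)].isna()
    if missing_ctrl.to_numpy().any():
        sample = ct.columns[missing_ctrl.any(axis=0)][0]
        gene = missing_ctrl.index[missing_ctrl.any(axis=1)][0]
        raise ValueError(f"control gene {gene!r} missing in sample {sample!r}")

    ctrl_mean = ct.loc[list(control_genes)].mean(axis=0)
    denom = 2.0 ** (ctrl_mean[testis_sample] - ctrl_mean)

    qc = records.set_index(["sample_id", "gene_id"])
    rows = []
    target_genes = [g for g in ct.index if g not in control_genes]
    for s in ct.columns:
        if s == testis_sample:
            continue
        for g in target_genes:
            rec = qc.loc[(s, g)]
            rec_t = qc.loc[(testis_sample, g)]
            ok = bool(rec["qc_pass"]) and bool(rec_t["qc_pass"])
            num = 2.0 ** (ct.loc[g, testis_sample] - ct.loc[g, s])
            ratio = num / denom[s] if ok else np.nan
            rows.append(
                {
                    "sample_id": s,
                    "gene_id": g,
                    "ratio": ratio,
                    "qc_pass": ok,
                    "qc_flags": list(rec["qc_flags"]) + list(rec_t["qc_flags"]),
                }
            )
    return pd.DataFrame(rows)


def qpcr_thresholds(normal_expr: pd.DataFrame, k: float = 2.0) -> pd.Series:
    """Per-gene aberrancy threshold: mean + k*SD of the normal-sample ratios.

    ``normal_expr`` is the :func:`relative_expression` output restricted to
    the normal samples (the study used 7 bone marrows + 3 cord bloods).
    """
    ok = normal_expr[normal_expr["qc_pass"]]
    counts = ok.groupby("gene_id")["ratio"].count()
    if (counts < 2).any() or ok.empty:
        bad = list(counts.index[counts < 2]) or ["<none>"]
        raise ValueError(f"need >= 2 normal samples per gene, short for: {bad}")
    grp = ok.groupby("gene_id")["ratio"]
    return grp.mean() + k * grp.std(ddof=1)


def classify_qpcr(
    expr: pd.DataFrame,
    thresholds: pd.Series,
    sig: SignatureGenes,
    frequent_genes: tuple = FREQUENT_GENES,
) -> pd.DataFrame:
    """Six-gene prognosis classification from qPCR ratios.

    Ratios are binarized at the per-gene qPCR thresholds (strictly above =
    expressed) and passed to the unchanged P1/P2/P3 rule.  Samples with any
    QC failure among the six prognostic genes are excluded and reported
    with ``klass='QC_FAIL'``.  When no prognostic gene is expressed, the
    ``quality_note`` reports whether any frequent control gene is expressed
    (``OK`` if so, ``LOW_CONFIDENCE`` otherwise — the sample may simply be
    poor material).
    """
    pivot = expr.pivot(index="gene_id", columns="sample_id", values="ratio")
    for g in sig.all_genes:
        if g not in pivot.index:
            raise ValueError(f"prognostic gene {g!r} not measured")
    qc_ok = (
        expr[expr["gene_id"].isin(sig.all_genes)]
        .groupby("sample_id")["qc_pass"]
        .all()
    )
    thr = thresholds.reindex(pivot.index)
    calls = pivot.gt(thr, axis=0)

    good = [s for s in calls.columns if qc_ok.get(s, False)]
    assign = _classify.assign_prognosis(calls[good], sig)
    notes = []
    for s in assign.index:
        if assign.loc[s, "npos"] + assign.loc[s, "nneg"] == 0:
            freq_on = any(
                bool(calls.loc[g, s])
                for g in frequent_genes
                if g in calls.index and pd.notna(pivot.loc[g, s])
            )
            notes.append("OK" if freq_on else "LOW_CONFIDENCE")
        else:
            notes.append("OK")
    assign["quality_note"] = notes

    failed = [s for s in calls.columns if not qc_ok.get(s, False)]
    if failed:
        fail_df = pd.DataFrame(
            {
                "npos": 0,
                "nneg": 0,
                "klass": "QC_FAIL",
                "group": "QC_FAIL",
                "quality_note": "QC_FAIL",
            },
            index=pd.Index(failed, name="sample_id"),
        )
        assign = pd.concat([assign, fail_df])
    return assign
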