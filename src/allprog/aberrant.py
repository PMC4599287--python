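"""Per-gene activation thresholds and binary aberrant-expression calls.

Each gene gets a threshold from a reference panel of normal samples::

    T_g = mean_ref(g) + k * sd_ref(g)

with k = 3 for microarray intensities (the reference being normal somatic
tissues) and k = 2 for qPCR ratios.  Tumor expression is then binarized:
a sample *expresses* the gene iff its value is strictly above T_g.  Genes
aberrantly expressed in fewer than ``min_freq`` of the tumors of any cohort
are filtered out of the screen.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def compute_thresholds(ref_matrix: pd.DataFrame, k: float = 3.0) -> pd.DataFrame:
    """Per-gene activation thresholds from a reference (normal) matrix.

    Returns a DataFrame indexed by gene id with columns
    ``ref_mean``, ``ref_sd`` (sample SD, n-1 denominator), ``k``,
    ``threshold`` and ``n_ref``.
    """
    if k <= 0:
        raise ValueError("k must be > 0")
    n_ref = ref_matrix.shape[1]
    if n_ref < 2:
        raise ValueError("need >= 2 reference samples (SD undefined for one)")
    mu = ref_matrix.mean(axis=1)
    sd = ref_matrix.std(axis=1, ddof=1)
    return pd.DataFrame(
        {
            "ref_mean": mu,
            "ref_sd": sd,
            "k": float(k),
            "threshold": mu + k * sd,
            "n_ref": n_ref,
        },
        index=ref_matrix.index,
    )


def binarize(matrix: pd.DataFrame, thresholds: pd.DataFrame) -> pd.DataFrame:
    """Boolean call matrix: call(g, s) is True iff x_{g,s} > T_g (strict).

    Values exactly at the threshold are "not expressed".  Every gene in
    ``matrix`` must have a threshold.
    """
    missing = matrix.index.difference(thresholds.index)
    if len(missing):
        raise ValueError(f"genes without thresholds: {list(missing)}")
    thr = thresholds.loc[matrix.index, "threshold"]
    return matrix.gt(thr, axis=0)


def call_frequencies(calls: pd.DataFrame) -> pd.Series:
    """Fraction of samples expressing each gene."""
    return calls.mean(axis=1)


def frequency_filter(
    calls_per_cohort: list[pd.DataFrame], min_freq: float = 0.10
) -> list:
    """Genes aberrantly expressed in at least ``min_freq`` of EVERY cohort.

    The boundary is inclusive: a gene at exactly 10% in both cohorts is
    retained (the filter removes genes expressed in *less than* 10%).
    Only genes present in all cohorts' call matrices are eligible.
    """
    if not calls_per_cohort:
        raise ValueError("need at least one cohort")
    if not 0 < min_freq < 1:
        raise ValueError("min_freq must be in (0, 1)")
    for c in calls_per_cohort:
        if c.shape[1] == 0:
            raise ValueError("empty cohort (no samples)")
    common = calls_per_cohort[0].index
    for c in calls_per_cohort[1:]:
        common = common.intersection(c.index)
    keep = np.ones(len(common), dtype=bool)
    for c in calls_per_cohort:
        keep &= (call_frequencies(c.loc[common]) >= min_freq).to_numpy()
    return list(common[keep])
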