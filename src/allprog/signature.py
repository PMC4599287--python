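"""Supervised transcriptomic characterization of the poor-outcome class.

Three steps:

* per-gene two-sided Mann-Whitney tests between P3 and P1&2 patients, with
  Benjamini-Hochberg adjustment (configurable off), genes split into
  up-in-P3 / down-in-P3 by the sign of the mean log-expression difference;
* detection of "P3-like" good-prognosis patients whose signature-restricted
  profile correlates more with the P3 centroid than with the P1&2 centroid
  (a reproducible surrogate for a visual heatmap call);
* weighted Kolmogorov-Smirnov (WKS) gene-set enrichment on the
  fold-change-ranked gene list: the enrichment score is the supremum of the
  centered cumulated-weight process, and p-values come from a seeded
  gene-label permutation null.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def differential_expression(
    matrix: pd.DataFrame,
    assignments: pd.DataFrame,
    alpha: float = 0.01,
    adjust: str | None = "fdr_bh",
) -> pd.DataFrame:
    """Two-sided Mann-Whitney test per gene, P3 vs P1&2.

    Returns a DataFrame indexed by gene id with ``u_statistic``, ``p_raw``,
    ``p_adjusted`` (equal to ``p_raw`` when ``adjust`` is None),
    ``fold_change`` (mean log-expression in P3 minus mean in P1&2),
    ``direction`` and ``significant`` (p_adjusted < alpha).  Constant genes
    get p = 1.
    """
    samples = assignments.index.intersection(matrix.columns)
    groups = assignments.loc[samples, "group"]
    p3 = matrix.loc[:, samples[groups == "P3"]]
    p12 = matrix.loc[:, samples[groups == "P1&2"]]
    if p3.shape[1] < 3 or p12.shape[1] < 3:
        raise ValueError("both groups need >= 3 samples")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.mannwhitneyu(
            p3.to_numpy(), p12.to_numpy(), axis=1, alternative="two-sided"
        )
    p_raw = np.asarray(res.pvalue, dtype=float)
    # a constant gene carries no rank information: force p = 1
    const = matrix.loc[:, samples].nunique(axis=1).to_numpy() == 1
    p_raw[const] = 1.0
    if adjust is None:
        p_adj = p_raw.copy()
    else:
        p_adj = multipletests(p_raw, method=adjust)[1]
    fc = p3.mean(axis=1) - p12.mean(axis=1)
    out = pd.DataFrame(
        {
            "u_statistic": np.asarray(res.statistic, dtype=float),
            "p_raw": p_raw,
            "p_adjusted": p_adj,
            "fold_change": fc,
        },
        index=matrix.index,
    )
    out["direction"] = np.where(out["fold_change"] > 0, "up_in_P3", "down_in_P3")
    out["significant"] = out["p_adjusted"] < alpha
    return out


def make_ranked_list(de: pd.DataFrame) -> pd.Series:
    """Fold-change-ranked gene list (descending) with fold changes as
    weights, for pre-ranked enrichment."""
    ranked = de["fold_change"].sort_values(ascending=False, kind="stable")
    ranked.index.name = "gene_id"
    return ranked


def detect_p3_like(
    matrix: pd.DataFrame, assignments: pd.DataFrame, de_genes: list
) -> list:
    """Good-prognosis (P1&2) samples with a P3-like signature profile.

    Over the differential-expression signature genes, a P1&2 sample is
    flagged when its Pearson correlation to the P3 centroid strictly
    exceeds its correlation to the P1&2 centroid (ties are not flagged).
    The P1&2 centroid is computed leaving the tested sample out, so a
    sample cannot shield itself by pulling its own group's centroid.
    """
    if not list(de_genes):
        raise ValueError("empty differential-expression signature")
    samples = assignments.index.intersection(matrix.columns)
    groups = assignments.loc[samples, "group"]
    p3_samples = samples[groups == "P3"]
    p12_samples = samples[groups == "P1&2"]
    if len(p3_samples) < 2 or len(p12_samples) < 2:
        raise ValueError("need >= 2 samples per prognosis group")
    sub = matrix.loc[list(de_genes), samples]
    cent_p3 = sub[p3_samples].mean(axis=1)
    p12_sum = sub[p12_samples].sum(axis=1)
    k = len(p12_samples)
    flagged = []
    for s in p12_samples:
        prof = sub[s]
        cent_p12 = (p12_sum - prof) / (k - 1)  # leave-one-out centroid
        r3 = np.corrcoef(prof, cent_p3)[0, 1]
        r12 = np.corrcoef(prof, cent_p12)[0, 1]
        if r3 > r12:
            flagged.append(s)
    return flagged


# ---------------------------------------------------------------------------
# Weighted Kolmogorov-Smirnov enrichment


def _wks_score(
    positions: np.ndarray, weights: np.ndarray, csum: np.ndarray, m_over_n: float
) -> np.ndarray:
    """Supremum of |centered cumulated-weight process| for one or many sets.

    The process is X(k) = sum of set-member weights among the top k ranks
    minus (m/N) times the cumulated weight of all genes up to k; it jumps at
    set-member positions and drifts in between, so its extrema over the
    whole list lie on the jump skeleton: X evaluated at each member position
    and just before it.  ``positions`` is (..., m), sorted ascending along
    the last axis; returns the per-row supremum.
    """
    v = np.take(weights, positions)
    V = np.cumsum(v, axis=-1)
    c_at = np.take(csum, positions + 1)
    c_before = np.take(csum, positions)
    x_at = V - m_over_n * c_at
    x_before = (V - v) - m_over_n * c_before
    return np.maximum(np.abs(x_at), np.abs(x_before)).max(axis=-1)


def wks_enrichment(
    ranked: pd.Series,
    gene_sets: dict,
    n_perm: int = 999,
    seed: int = 0,
    min_size: int = 5,
) -> pd.DataFrame:
    """Weighted-KS enrichment of gene sets in a fold-change-ranked list.

    ``ranked`` maps gene id -> weight, ordered by decreasing weight.  Each
    gene set is intersected with the ranked universe (sets with fewer than
    ``min_size`` members after intersection are skipped with a warning).
    The enrichment score is the supremum of the centered cumulated-weight
    process (see :func:`_wks_score`), normalized by the weight scale so that
    rescaling all weights leaves scores comparable; the p-value compares the
    observed score with ``n_perm`` random same-size sets drawn with the
    given seed, p = (1 + #{null >= observed}) / (n_perm + 1), so p is in
    (0, 1] and identical seeds give identical p-values.

    Returns a DataFrame indexed by gene-set id with ``enrichment_score``,
    ``p_value``, ``size`` and ``direction`` (sign of the process at its
    supremum: "up" if the set is enriched among positive weights).
    """
    rng = np.random.default_rng(seed)
    genes = list(ranked.index)
    w = ranked.to_numpy(dtype=float)
    n = len(w)
    scale = np.sqrt((w**2).mean()) or 1.0
    w = w / scale
    csum = np.concatenate(([0.0], np.cumsum(w)))
    pos_of = {g: i for i, g in enumerate(genes)}

    rows = []
    for name, members in gene_sets.items():
        positions = np.sort([pos_of[g] for g in members if g in pos_of])
        m = len(positions)
        if m < min_size:
            warnings.warn(
                f"gene set {name!r}: only {m} members in the ranked universe; skipped",
                stacklevel=2,
            )
            continue
        m_over_n = m / n
        obs = float(_wks_score(positions, w, csum, m_over_n))
        # direction: sign of the centered process at its supremum
        v = w[positions]
        V = np.cumsum(v)
        x_at = V - m_over_n * csum[positions + 1]
        x_before = (V - v) - m_over_n * csum[positions]
        allx = np.concatenate([x_at, x_before])
        direction = "up" if allx[np.abs(allx).argmax()] >= 0 else "down"

        null_pos = np.sort(
            rng.random((n_perm, n)).argpartition(m - 1, axis=1)[:, :m], axis=1
        ) if m < n else np.tile(np.arange(n), (n_perm, 1))
        null = _wks_score(null_pos, w, csum, m_over_n)
        p = float((1 + (null >= obs).sum()) / (n_perm + 1))
        rows.append(
            {
                "gene_set_id": name,
                "enrichment_score": obs,
                "p_value": p,
                "size": m,
                "direction": direction,
            }
        )
    return pd.DataFrame(rows).set_index("gene_set_id") if rows else pd.DataFrame(
        columns=["enrichment_score", "p_value", "size", "direction"]
    )
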