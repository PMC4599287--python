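"""Per-gene survival screening and cross-cohort signature selection.

For every candidate gene, patients are split into expressers and
non-expressers of the binarized call and their overall survival is
compared with a logrank (Mantel-Cox) test; the hazard ratio (expressers
vs non-expressers, HR > 1 meaning expressers die faster) is estimated by
a univariate Cox proportional-hazards fit of the binary call.

Genes are then screened across cohorts: a gene is retained when its HR
direction is consistent in every cohort and its logrank p-value is below
alpha in every cohort.  Retained genes are split by direction, ranked by
increasing p-value (by default the maximum over cohorts, so the rank
respects the everywhere-significant rule) and the top ``n_top`` of each
direction form the prognostic signature.

The Cox fit is a dedicated Newton solver for the one-parameter partial
likelihood with Breslow tie handling; it matches lifelines.CoxPHFitter to
numerical precision (see the test suite) and is ~100x faster, which is
what makes screening thousands of gene/cohort combinations cheap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .classify import SignatureGenes

_BETA_CAP = 15.0  # |log HR| cap under monotone likelihood (complete separation)


@dataclass
class _SortedSurvival:
    """Pre-sorted survival arrays shared across the per-gene loop."""

    order: np.ndarray
    event: np.ndarray  # sorted by time ascending
    first: np.ndarray  # first index of each unique time block
    n_at: np.ndarray  # at-risk count per block
    d: np.ndarray  # events per block

    @classmethod
    def from_arrays(cls, time: np.ndarray, event: np.ndarray) -> "_SortedSurvival":
        order = np.argsort(time, kind="stable")
        t = time[order]
        e = event[order].astype(float)
        _, first = np.unique(t, return_index=True)
        n_at = len(t) - first
        d = np.add.reduceat(e, first)
        return cls(order=order, event=e, first=first, n_at=n_at, d=d)


def _logrank_and_cox(ss: _SortedSurvival, x_sorted: np.ndarray):
    """Logrank chi-square p and Cox log-HR for one binary covariate.

    ``x_sorted`` is the 0/1 expresser indicator already in time order.
    Returns (log_hr, logrank_p).
    """
    csum = np.concatenate(([0.0], np.cumsum(x_sorted)))
    n1 = x_sorted.sum() - csum[ss.first]  # at-risk expressers per block
    s = np.add.reduceat(ss.event * x_sorted, ss.first)  # expresser deaths
    n, d = ss.n_at, ss.d
    ev = d > 0
    n, d, n1, s = n[ev], d[ev], n1[ev], s[ev]
    n0 = n - n1

    # Mantel-Cox: observed minus expected expresser deaths, hypergeometric var
    frac = n1 / n
    o_minus_e = (s - d * frac).sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        var_terms = d * frac * (1 - frac) * (n - d) / (n - 1)
    v = var_terms[n > 1].sum()
    if v <= 0:
        logrank_p = 1.0
    else:
        logrank_p = float(stats.chi2.sf(o_minus_e**2 / v, df=1))

    # Newton on the Breslow partial likelihood, beta = log HR
    beta = 0.0
    for _ in range(60):
        eb = np.exp(beta)
        denom = n0 + n1 * eb
        mu = n1 * eb / denom
        score = (s - d * mu).sum()
        info = (d * mu * (1 - mu)).sum()
        if info <= 0:
            beta = np.sign(score) * _BETA_CAP if score != 0 else 0.0
            break
        step = score / info
        beta = float(np.clip(beta + step, -_BETA_CAP, _BETA_CAP))
        if abs(step) < 1e-10 or abs(beta) >= _BETA_CAP:
            break
    return beta, logrank_p


def gene_survival_test(
    calls: pd.DataFrame, surv: pd.DataFrame, gene_id: str
) -> dict:
    """Expressers-vs-non-expressers survival test for one gene.

    Returns a dict with ``hr``, ``logrank_p``, ``n_expressers``, ``n`` and
    ``testable``.  A gene whose expresser or non-expresser group is empty
    is flagged ``testable=False`` (hr and p are NaN) rather than raising.
    """
    table = screen_genes(calls.loc[[gene_id]], surv)
    return table.iloc[0].to_dict() | {"gene_id": gene_id}


def screen_genes(
    calls: pd.DataFrame, surv: pd.DataFrame, genes=None
) -> pd.DataFrame:
    """Run :func:`gene_survival_test` for every gene of a call matrix.

    ``calls`` is the boolean genes x samples matrix; ``surv`` must contain
    ``time`` and ``event`` indexed by sample id (every call-matrix sample
    present).  Returns a DataFrame indexed by gene id with columns
    ``hr``, ``logrank_p``, ``n_expressers``, ``n``, ``testable``.
    """
    if genes is None:
        genes = list(calls.index)
    samples = list(calls.columns)
    missing = set(samples) - set(surv.index)
    if missing:
        raise ValueError(f"samples without survival data: {sorted(missing)}")
    if len(samples) < 10:
        raise ValueError("survival screen requires n >= 10")
    time = surv.loc[samples, "time"].to_numpy(float)
    event = surv.loc[samples, "event"].to_numpy(bool)
    ss = _SortedSurvival.from_arrays(time, event)

    x_all = calls.loc[genes, samples].to_numpy(bool).astype(float)
    rows = np.empty((len(genes), 4))
    for i in range(len(genes)):
        x = x_all[i]
        n_expr = int(x.sum())
        if n_expr == 0 or n_expr == len(x):
            rows[i] = (np.nan, np.nan, n_expr, 0)
            continue
        beta, p = _logrank_and_cox(ss, x[ss.order])
        rows[i] = (np.exp(beta), p, n_expr, 1)
    out = pd.DataFrame(
        rows,
        index=pd.Index(genes, name="gene_id"),
        columns=["hr", "logrank_p", "n_expressers", "testable"],
    )
    out["n"] = len(samples)
    out["n_expressers"] = out["n_expressers"].astype(int)
    out["testable"] = out["testable"].astype(bool)
    return out[["hr", "logrank_p", "n_expressers", "n", "testable"]]


def combine_cohorts(results: list[pd.DataFrame], alpha: float = 0.05) -> pd.DataFrame:
    """Join per-cohort screen tables and add cross-cohort consistency flags.

    Columns ``hr_<i>``/``p_<i>`` per cohort plus ``direction_consistent``
    (all HRs on the same side of 1), ``significant_both`` (logrank p < alpha
    in every cohort), ``direction`` ("negative" for HR > 1, i.e. associated
    with shorter survival) and ``rank_p`` (the maximum p over cohorts).
    """
    if len(results) < 2:
        raise ValueError("cross-cohort screening needs >= 2 cohorts")
    common = results[0].index
    for r in results[1:]:
        common = common.intersection(r.index)
    out = pd.DataFrame(index=common)
    hrs, ps = [], []
    for i, r in enumerate(results):
        r = r.loc[common]
        out[f"hr_{i}"] = r["hr"]
        out[f"p_{i}"] = r["logrank_p"]
        out[f"testable_{i}"] = r["testable"]
        hrs.append(r["hr"])
        ps.append(r["logrank_p"])
    hr_mat = np.column_stack([h.to_numpy() for h in hrs])
    p_mat = np.column_stack([p.to_numpy() for p in ps])
    testable = np.column_stack([out[f"testable_{i}"] for i in range(len(results))]).all(axis=1)
    out["direction_consistent"] = testable & (
        (hr_mat > 1).all(axis=1) | (hr_mat < 1).all(axis=1)
    )
    out["significant_both"] = testable & (p_mat < alpha).all(axis=1)
    direction = np.where(hr_mat.mean(axis=1) > 1, "negative", "positive")
    direction = np.where(testable, direction, "untestable")
    out["direction"] = direction
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        out["rank_p"] = np.nanmax(p_mat, axis=1)
    return out


def cross_cohort_select(
    results: list[pd.DataFrame],
    n_top: int = 3,
    alpha: float = 0.05,
    rank_key: str = "max_p",
) -> tuple[SignatureGenes, pd.DataFrame]:
    """Select the top prognostic genes consistent across all cohorts.

    Eligible genes are direction-consistent with logrank p < ``alpha`` in
    every cohort.  Within each direction they are ranked by increasing
    p-value — ``rank_key`` picks the combining rule: ``"max_p"`` (default;
    the largest cohort p, honoring the everywhere-significant criterion),
    ``"mean_p"`` or ``"first"`` (learning-cohort p only) — with ties broken
    by gene id.  Returns the signature (positive = HR < 1, negative =
    HR > 1) and the full combined table.
    """
    table = combine_cohorts(results, alpha=alpha)
    if rank_key == "max_p":
        key = table["rank_p"]
    elif rank_key == "mean_p":
        key = table[[c for c in table if c.startswith("p_")]].mean(axis=1)
    elif rank_key == "first":
        key = table["p_0"]
    else:
        raise ValueError(f"unknown rank_key {rank_key!r}")
    table = table.assign(rank_p=key)
    eligible = table[table["direction_consistent"] & table["significant_both"]]
    picks = {}
    for direction in ("positive", "negative"):
        sub = eligible[eligible["direction"] == direction]
        # sort by gene id first so the stable p-value sort breaks ties by id
        sub = sub.sort_index(kind="stable").sort_values("rank_p", kind="stable")
        if len(sub) < n_top:
            warnings.warn(
                f"only {len(sub)} eligible {direction} genes (requested {n_top})",
                stacklevel=2,
            )
        picks[direction] = list(sub.index[:n_top])
    sig = SignatureGenes(positive=picks["positive"], negative=picks["negative"])
    return sig, table
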