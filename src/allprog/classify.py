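"""Six-gene P1/P2/P3 prognosis classification and survival comparisons.

The classifier counts, per patient, how many of the three "positive" genes
(aberrant expression associated with longer survival) and three "negative"
genes (associated with shorter survival) are expressed:

* **P1** — no negative gene and at least two positive genes (best outcome);
* **P3** — at least one negative gene and at most one positive gene
  (poorest outcome);
* **P2** — everything else (>=1 negative with >=2 positive, or no negative
  with <2 positive).

P1 and P2 merge into the good-prognosis group **P1&2**; the final contrast
is P1&2 vs P3.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test, proportional_hazard_test
from scipy import stats


@dataclass
class SignatureGenes:
    """The prognostic gene panel: positive = protective (HR < 1),
    negative = hazardous (HR > 1)."""

    positive: list
    negative: list

    def __post_init__(self):
        if set(self.positive) & set(self.negative):
            raise ValueError("positive and negative gene lists must be disjoint")

    @property
    def complete(self) -> bool:
        """Both directions populated (a screen that came up short of
        eligible genes returns an incomplete signature with a warning)."""
        return bool(self.positive) and bool(self.negative)

    @property
    def all_genes(self) -> list:
        return list(self.positive) + list(self.negative)


def classify_counts(npos: int, nneg: int) -> str:
    """P1/P2/P3 from the expressed-gene counts."""
    if nneg >= 1 and npos <= 1:
        return "P3"
    if nneg == 0 and npos >= 2:
        return "P1"
    return "P2"


def assign_prognosis(calls: pd.DataFrame, sig: SignatureGenes) -> pd.DataFrame:
    """Classify every sample of a boolean call matrix.

    Returns a DataFrame indexed by sample id with columns ``npos``, ``nneg``,
    ``klass`` (P1/P2/P3) and ``group`` (P1&2 or P3).
    """
    if not sig.complete:
        raise ValueError("classification needs both positive and negative genes")
    for g in sig.all_genes:
        if g not in calls.index:
            raise ValueError(f"signature gene {g!r} missing from the call matrix")
    npos = calls.loc[list(sig.positive)].sum(axis=0).astype(int)
    nneg = calls.loc[list(sig.negative)].sum(axis=0).astype(int)
    klass = [classify_counts(p, n) for p, n in zip(npos, nneg)]
    out = pd.DataFrame(
        {"npos": npos, "nneg": nneg, "klass": klass},
        index=calls.columns.rename("sample_id"),
    )
    out["group"] = np.where(out["klass"] == "P3", "P3", "P1&2")
    return out


@dataclass
class KMComparison:
    """Kaplan-Meier comparison of P3 vs P1&2, optionally within a stratum."""

    testable: bool
    p_value: float = np.nan
    n_p3: int = 0
    n_p12: int = 0
    fitters: dict = field(default_factory=dict)
    reason: str = ""


def compare_groups_km(
    assignments: pd.DataFrame,
    surv: pd.DataFrame,
    stratum: pd.Series | None = None,
    horizon: float | None = None,
) -> KMComparison:
    """Compare P3 vs P1&2 survival with Kaplan-Meier curves and a logrank test.

    ``stratum`` is an optional boolean Series (indexed by sample id)
    restricting the comparison to a covariate-defined subgroup.  ``horizon``
    administratively censors at the given time (e.g. 5 years).  Returns an
    untestable result, never raises, when a group is empty.
    """
    samples = assignments.index.intersection(surv.index)
    df = assignments.loc[samples].join(surv.loc[samples, ["time", "event"]])
    if stratum is not None:
        df = df[stratum.reindex(samples).fillna(False).astype(bool)]
    if horizon is not None:
        over = df["time"] > horizon
        df = df.assign(
            event=df["event"] & ~over, time=df["time"].clip(upper=horizon)
        )
    in_p3 = df["group"] == "P3"
    n_p3, n_p12 = int(in_p3.sum()), int((~in_p3).sum())
    if n_p3 == 0 or n_p12 == 0:
        return KMComparison(
            testable=False, n_p3=n_p3, n_p12=n_p12, reason="a prognosis group is empty"
        )
    fitters = {}
    for name, sub in (("P3", df[in_p3]), ("P1&2", df[~in_p3])):
        kmf = KaplanMeierFitter(label=name)
        kmf.fit(sub["time"], sub["event"])
        fitters[name] = kmf
    res = logrank_test(
        df.loc[in_p3, "time"],
        df.loc[~in_p3, "time"],
        event_observed_A=df.loc[in_p3, "event"],
        event_observed_B=df.loc[~in_p3, "event"],
    )
    return KMComparison(
        testable=True, p_value=float(res.p_value), n_p3=n_p3, n_p12=n_p12, fitters=fitters
    )


def tabulate_by_subtype(
    assignments: pd.DataFrame, subtype_labels: pd.Series
) -> pd.DataFrame:
    """Per-subtype counts of P1&2 and P3 patients and the P3 fraction."""
    labels = subtype_labels.reindex(assignments.index)
    if labels.isna().any():
        raise ValueError(
            f"samples without subtype label: {list(assignments.index[labels.isna()])}"
        )
    tab = (
        pd.crosstab(labels, assignments["group"])
        .reindex(columns=["P1&2", "P3"], fill_value=0)
    )
    tab["n"] = tab.sum(axis=1)
    tab["p3_fraction"] = tab["P3"] / tab["n"]
    return tab


def format_fraction(count: int, total: int, label: str = "P3") -> str:
    """Report line with the percentage rounded to the nearest integer,
    e.g. ``P3: 61/207 (29%)``."""
    pct = int(round(100.0 * count / total))
    return f"{label}: {count}/{total} ({pct}%)"


# ---------------------------------------------------------------------------
# Multivariate Cox wrapper


def _univariate_p(df: pd.DataFrame, var: str) -> float:
    """Univariate screen p-value: logrank for a binary variable, Cox
    likelihood-ratio otherwise.  Degenerate (constant) variables get p = 1."""
    vals = df[var]
    uniq = vals.unique()
    if len(uniq) < 2:
        return 1.0
    if len(uniq) == 2:
        a = df[vals == uniq[0]]
        b = df[vals == uniq[1]]
        res = logrank_test(
            a["time"], b["time"], event_observed_A=a["event"], event_observed_B=b["event"]
        )
        return float(res.p_value)
    cph = CoxPHFitter()
    cph.fit(df[["time", "event", var]], "time", "event")
    return float(cph.log_likelihood_ratio_test().p_value)


def _fit(df: pd.DataFrame, variables: list) -> CoxPHFitter:
    cph = CoxPHFitter()
    cph.fit(df[["time", "event"] + list(variables)], "time", "event")
    return cph


def _ic(cph: CoxPHFitter, k: int, n_events: int, kind: str) -> float:
    penalty = 2 * k if kind == "aic" else k * np.log(max(n_events, 1))
    return -2 * cph.log_likelihood_ + penalty


def _backward(df: pd.DataFrame, variables: list, n_events: int, kind: str) -> list:
    current = list(variables)
    best = _ic(_fit(df, current), len(current), n_events, kind) if current else np.inf
    while current:
        trial = [
            (v, _ic(_fit(df, [w for w in current if w != v]), len(current) - 1, n_events, kind))
            for v in current
        ]
        v, score = min(trial, key=lambda t: t[1])
        if score < best:
            best = score
            current = [w for w in current if w != v]
        else:
            break
    return current


def _null_loglik(df: pd.DataFrame) -> float:
    """Breslow partial log-likelihood of the covariate-free Cox model."""
    t = df["time"].to_numpy(float)
    e = df["event"].to_numpy(bool).astype(float)
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    _, first = np.unique(t, return_index=True)
    n_at = len(t) - first
    d = np.add.reduceat(e, first)
    return float(-(d * np.log(n_at)).sum())


def likelihood_ratio_test(ll_full: float, ll_nested: float, df_diff: int) -> float:
    """LRT p-value between embedded Cox models (chi-square reference)."""
    lr = 2 * (ll_full - ll_nested)
    return float(stats.chi2.sf(max(lr, 0.0), df=max(df_diff, 1)))


def multivariate_cox(
    surv: pd.DataFrame,
    assignments: pd.DataFrame,
    covariates: list,
    screen_p: float = 0.20,
) -> dict:
    """Multivariate prognostic model of the P3-vs-P1&2 indicator.

    Procedure: (i) univariate screen of the candidate variables (the
    covariates plus the ``P3vsP1&2`` indicator) at p < ``screen_p``;
    (ii) Cox proportional-hazards fit on the retained set; (iii) backward
    elimination separately under AIC and BIC; (iv) likelihood-ratio tests
    of the full model against each single-variable deletion (embedded
    models); (v) Schoenfeld-residual proportional-hazards diagnostic.

    Returns a dict with keys ``univariate_p``, ``retained``, ``model``
    (lifelines fitter or None), ``aic_selected``, ``bic_selected``,
    ``lrt_vs_drop`` and ``schoenfeld_p``.  Non-convergent fits are reported
    per variable under ``failed``, not raised.
    """
    samples = assignments.index.intersection(surv.index)
    df = surv.loc[samples, ["time", "event"] + list(covariates)].copy()
    df["event"] = df["event"].astype(int)
    df["P3vsP1&2"] = (assignments.loc[samples, "group"] == "P3").astype(int)
    candidates = list(covariates) + ["P3vsP1&2"]
    if len(candidates) < 2:
        raise ValueError("need >= 2 candidate variables")
    n_events = int(df["event"].sum())
    if n_events < 10:
        raise ValueError("need >= 10 events for the multivariate model")

    uni = {v: _univariate_p(df, v) for v in candidates}
    retained = [v for v in candidates if uni[v] < screen_p]

    report = {
        "univariate_p": uni,
        "retained": retained,
        "model": None,
        "aic_selected": [],
        "bic_selected": [],
        "lrt_vs_drop": {},
        "schoenfeld_p": {},
        "failed": {},
    }
    if not retained:
        return report
    try:
        model = _fit(df, retained)
    except Exception as exc:  # non-convergence is reported, not fatal
        report["failed"]["full_model"] = str(exc)
        return report
    report["model"] = model
    for kind in ("aic", "bic"):
        try:
            report[f"{kind}_selected"] = _backward(df, retained, n_events, kind)
        except Exception as exc:
            report["failed"][f"{kind}_backward"] = str(exc)
    for v in retained:
        rest = [w for w in retained if w != v]
        try:
            ll_nested = _fit(df, rest).log_likelihood_ if rest else _null_loglik(df)
            report["lrt_vs_drop"][v] = likelihood_ratio_test(
                model.log_likelihood_, ll_nested, 1
            )
        except Exception as exc:
            report["failed"][v] = str(exc)
    try:
        ph = proportional_hazard_test(model, df[["time", "event"] + retained])
        report["schoenfeld_p"] = ph.summary["p"].to_dict()
    except Exception as exc:
        report["failed"]["schoenfeld"] = str(exc)
    return report
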