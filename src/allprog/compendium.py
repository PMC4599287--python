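"""Tissue-predominance calling over a multi-tissue expression compendium.

The compendium is a log-scale normalized expression matrix (genes x samples)
whose samples are annotated with one of five tissue groups: ``germline``,
``es`` (embryonic stem cells), ``placenta``, ``somatic`` (normal adult
somatic tissues) and ``bm_nonleukemic`` (non-leukemic bone marrow).

A gene is called *predominantly expressed* outside somatic tissue when its
maximum expression across the germline/ES/placenta/somatic panel exceeds the
somatic baseline by more than three standard deviations::

    max_g  >  mean_somatic(g) + 3 * sd_somatic(g)

and the maximum is not attained in the somatic group.  Genes passing this
rule and additionally never exceeding their activation threshold in any
non-leukemic bone-marrow sample are the *normally silent* genes that the
downstream tumor screen operates on.
"""

from __future__ import annotations

import pandas as pd

#: tissue groups eligible for predominance (and their tie-break priority)
NON_SOMATIC_GROUPS = ("germline", "es", "placenta")
GROUP_ORDER = ("germline", "es", "placenta", "somatic")
ALL_GROUPS = GROUP_ORDER + ("bm_nonleukemic",)


class MissingGroupError(ValueError):
    """A required tissue group is absent from the annotation."""

    def __init__(self, group: str):
        self.group = group
        super().__init__(f"tissue group {group!r} has no samples in the annotation")


def _group_columns(matrix: pd.DataFrame, ann: pd.Series) -> dict[str, list]:
    ann = ann.reindex(matrix.columns)
    if ann.isna().any():
        missing = list(matrix.columns[ann.isna()])
        raise ValueError(f"samples without tissue annotation: {missing}")
    bad = set(ann.unique()) - set(ALL_GROUPS)
    if bad:
        raise ValueError(f"unknown tissue groups: {sorted(bad)}")
    return {g: list(matrix.columns[ann == g]) for g in ALL_GROUPS}


def call_predominance(
    matrix: pd.DataFrame,
    ann: pd.Series,
    k: float = 3.0,
    baseline: str = "somatic",
) -> pd.DataFrame:
    """Call per-gene tissue predominance.

    Parameters
    ----------
    matrix
        Log-scale expression, genes as rows, samples as columns.
    ann
        Maps sample id -> tissue group.
    k
        Standard-deviation multiplier of the predominance threshold.
    baseline
        ``"somatic"`` (default): mean/SD computed over somatic samples only.
        ``"all"``: computed over all four compendium groups (variant reading
        of the rule; bone marrow is never part of the baseline).

    Returns
    -------
    DataFrame indexed by gene id with columns ``somatic_mean``, ``somatic_sd``,
    ``max_value``, ``max_group``, ``predominant``.  Ties for the maximum group
    are broken in the fixed order germline > es > placenta > somatic.
    """
    if baseline not in ("somatic", "all"):
        raise ValueError("baseline must be 'somatic' or 'all'")
    cols = _group_columns(matrix, ann)
    for g in GROUP_ORDER:
        if not cols[g]:
            raise MissingGroupError(g)
    if len(cols["somatic"]) < 2:
        raise ValueError("need >= 2 somatic samples to estimate the baseline SD")

    somatic = matrix[cols["somatic"]]
    if baseline == "somatic":
        base = somatic
    else:
        base = matrix[[c for g in GROUP_ORDER for c in cols[g]]]
    mu = base.mean(axis=1)
    sd = base.std(axis=1, ddof=1)

    # per-group maxima; overall max and its group with fixed tie-break order
    group_max = pd.DataFrame(
        {g: matrix[cols[g]].max(axis=1) for g in GROUP_ORDER}
    )
    max_value = group_max.max(axis=1)
    # idxmax on the ordered columns breaks ties by the fixed priority
    max_group = group_max[list(GROUP_ORDER)].idxmax(axis=1)

    predominant = (max_value > mu + k * sd) & (max_group != "somatic")
    return pd.DataFrame(
        {
            "somatic_mean": somatic.mean(axis=1),
            "somatic_sd": somatic.std(axis=1, ddof=1),
            "max_value": max_value,
            "max_group": max_group,
            "predominant": predominant,
        },
        index=matrix.index,
    )


def filter_bone_marrow_silent(
    calls: pd.DataFrame,
    matrix: pd.DataFrame,
    ann: pd.Series,
    thresholds: pd.DataFrame,
) -> list:
    """Retain predominant genes silent in every non-leukemic bone marrow.

    A gene is kept only if its expression is <= its activation threshold in
    *all* ``bm_nonleukemic`` samples; a single above-threshold marrow sample
    excludes it ("even sporadically expressed" genes are dropped).  Values
    exactly at the threshold count as silent, because expression requires
    being strictly above the threshold.

    ``thresholds`` must carry a ``threshold`` column indexed by gene id (as
    produced by :func:`allprog.aberrant.compute_thresholds`) covering every
    predominant gene.
    """
    cols = _group_columns(matrix, ann)
    bm = cols["bm_nonleukemic"]
    if not bm:
        raise MissingGroupError("bm_nonleukemic")
    pred_genes = calls.index[calls["predominant"]]
    missing = pred_genes.difference(thresholds.index)
    if len(missing):
        raise ValueError(f"no threshold for predominant genes: {list(missing)}")
    thr = thresholds.loc[pred_genes, "threshold"]
    bm_max = matrix.loc[pred_genes, bm].max(axis=1)
    silent = bm_max <= thr
    return list(pred_genes[silent])
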