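"""Synthetic inputs emulating the ALL aberrant-activation study design.

The generator produces, under one integer seed:

* a multi-tissue normal compendium (germline / ES / placenta / somatic /
  non-leukemic bone marrow) with a planted fraction of germline-, ES- or
  placenta-predominant genes, a subset of which are also expressed in bone
  marrow (and must therefore be filtered out of the "normally silent" list);
* tumor cohorts in which a subset of the silent genes is aberrantly
  activated in a Bernoulli fraction of patients, with exponential
  proportional-hazards survival in which activation of designated genes
  multiplies the hazard, plus independent exponential censoring;
* RT-qPCR Ct tables (duplicates, no-RT controls, a testis reference and
  four control genes) that invert exactly through the published ratio
  formula to planted relative-expression values.

Noise is additive Gaussian on a log2-like scale, truncated at
``noise_clip`` standard deviations (default 2).  The truncation guarantees the planted
truth is exactly recoverable by the mean + k*SD thresholding rules: every
background value stays below the threshold and every activated value above
it whenever ``activation_shift`` comfortably exceeds the noise scale.
Real microarray data has heavier tails; see docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

POSITIVE_GENES = ("CAMSAP1", "PCGF6", "SH3RF3")
NEGATIVE_GENES = ("AK022211", "FASTKD1", "STARD4")
FREQUENT_GENES = ("COX8C", "DKFZp761D1918", "RPL10L")
CONTROL_GENES = ("ACTB", "U6", "RELA", "AUP1")

_DEFAULT_TISSUES = {
    "germline": 18,
    "es": 6,
    "placenta": 10,
    "somatic": 112,
    "bm_nonleukemic": 74,
}

# baseline prevalences of the clinical covariates in a high-risk pediatric
# B-ALL cohort (order matches the multivariate model's nine variables)
_DEFAULT_COVARIATES = {
    "MLL": 0.10,
    "BCR_ABL": 0.05,
    "CRLF2_high": 0.23,
    "MRD_d29": 0.35,
    "IKZF1_mutdel": 0.28,
    "age_ge10": 0.50,
    "WBC_ge50": 0.40,
    "CNS": 0.10,
    "male": 0.55,
}


@dataclass
class SimConfig:
    """Study-level parameters for the synthetic bundle.

    Defaults mirror the study's shape: 112 somatic reference tissues, 74
    non-leukemic marrows, two tumor cohorts of 207 and 59 patients, roughly
    a third of genes predominant outside somatic tissue, 31% of those
    marrow-expressed, 29% of the silent genes activated in tumors, and
    three protective (hazard x0.4) plus three hazardous (x2.5) genes
    activated in ~30% of patients each.
    """

    seed: int = 0
    n_genes: int = 1200
    frac_predominant: float = 0.30
    frac_predominant_marrow_expressed: float = 0.31
    tissue_group_sizes: dict = field(default_factory=lambda: dict(_DEFAULT_TISSUES))
    cohort_sizes: tuple = (207, 59)
    frac_activated_genes: float = 0.29
    activation_freq: float = 0.30
    planted_positive_genes: tuple | None = None  # default: pick n_positive
    planted_negative_genes: tuple | None = None
    n_positive: int = 3
    n_negative: int = 3
    hr_positive: float = 0.4
    hr_negative: float = 2.5
    baseline_hazard: float = 0.06
    censor_rate: float = 0.03
    baseline_expr: float = 5.0
    noise_sd: float = 0.5
    activation_shift: float = 4.0
    noise_clip: float = 2.0
    covariate_freqs: dict = field(default_factory=lambda: dict(_DEFAULT_COVARIATES))

    def __post_init__(self):
        for name in (
            "frac_predominant",
            "frac_predominant_marrow_expressed",
            "frac_activated_genes",
            "activation_freq",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if any(n < 0 for n in self.tissue_group_sizes.values()):
            raise ValueError("tissue group sizes must be non-negative")
        if self.tissue_group_sizes.get("somatic", 0) < 2:
            raise ValueError("need >= 2 somatic samples")
        if self.hr_positive <= 0 or self.hr_negative <= 0:
            raise ValueError("hazard multipliers must be > 0")
        if self._n_planted("positive") and not self.hr_positive < 1:
            raise ValueError("hr_positive must be < 1 (protective) when planted")
        if self._n_planted("negative") and not self.hr_negative > 1:
            raise ValueError("hr_negative must be > 1 (hazardous) when planted")
        if self.activation_shift <= 3 * self.noise_sd:
            raise ValueError(
                "activation_shift must exceed 3*noise_sd "
                f"({self.activation_shift} <= {3 * self.noise_sd}): planted "
                "activation would be undetectable by the mean+3SD rule"
            )

    def _n_planted(self, direction: str) -> int:
        explicit = getattr(self, f"planted_{direction}_genes")
        if explicit is not None:
            return len(explicit)
        return getattr(self, f"n_{direction}")

    def rng(self, stream: int) -> np.random.Generator:
        """Deterministic sub-stream generator (stream 0 = compendium,
        1 + i = cohort i, 100 = qPCR)."""
        return np.random.default_rng([int(self.seed), int(stream)])


@dataclass
class SyntheticBundle:
    compendium: pd.DataFrame
    annotation: pd.Series
    cohorts: list  # list of (expression DataFrame, survival DataFrame, mask)
    truth: dict


def _noise(rng, shape, sd, clip):
    z = rng.standard_normal(shape)
    return np.clip(z, -clip, clip) * sd


def simulate_compendium(cfg: SimConfig):
    """Generate the normal-tissue compendium.

    Returns ``(matrix, annotation, truth)`` where truth holds the planted
    ``predominant`` genes with their home groups, the ``marrow_expressed``
    subset, the ``silent`` set (predominant minus marrow-expressed), the
    ``activated`` subset shared by all tumor cohorts, and the planted
    ``positive``/``negative`` prognostic genes.
    """
    rng = cfg.rng(0)
    genes = [f"G{i:04d}" for i in range(cfg.n_genes)]
    sample_ids, groups = [], []
    for g, n in cfg.tissue_group_sizes.items():
        for i in range(n):
            sample_ids.append(f"{g}_{i:03d}")
            groups.append(g)
    ann = pd.Series(groups, index=pd.Index(sample_ids, name="sample_id"), name="group")

    n_pred = int(round(cfg.frac_predominant * cfg.n_genes))
    pred_idx = rng.choice(cfg.n_genes, size=n_pred, replace=False)
    home_pool = [g for g in ("germline", "es", "placenta") if cfg.tissue_group_sizes.get(g, 0) > 0]
    homes = rng.choice(home_pool, size=n_pred) if n_pred else np.array([], dtype=object)
    n_marrow = int(round(cfg.frac_predominant_marrow_expressed * n_pred))
    marrow_idx = rng.choice(n_pred, size=n_marrow, replace=False) if n_pred else []

    values = cfg.baseline_expr + _noise(
        rng, (cfg.n_genes, len(sample_ids)), cfg.noise_sd, cfg.noise_clip
    )
    group_cols = {g: np.flatnonzero(ann.to_numpy() == g) for g in set(groups)}
    marrow_set = {int(x) for x in np.atleast_1d(marrow_idx)}
    for j, (gi, home) in enumerate(zip(pred_idx, homes)):
        values[gi, group_cols[home]] += cfg.activation_shift
        if j in marrow_set and "bm_nonleukemic" in group_cols:
            values[gi, group_cols["bm_nonleukemic"]] += cfg.activation_shift

    matrix = pd.DataFrame(values, index=pd.Index(genes, name="gene_id"), columns=sample_ids)

    predominant = {genes[gi]: str(home) for gi, home in zip(pred_idx, homes)}
    marrow_expressed = {genes[pred_idx[j]] for j in np.atleast_1d(marrow_idx)} if n_pred else set()
    silent = sorted(set(predominant) - marrow_expressed)
    n_act = int(round(cfg.frac_activated_genes * len(silent)))
    activated = sorted(str(g) for g in rng.choice(silent, size=n_act, replace=False)) if n_act else []

    if cfg.planted_positive_genes is not None:
        positive = [str(g) for g in cfg.planted_positive_genes]
    else:
        positive = list(activated[: cfg.n_positive])
    if cfg.planted_negative_genes is not None:
        negative = [str(g) for g in cfg.planted_negative_genes]
    else:
        negative = list(activated[cfg.n_positive : cfg.n_positive + cfg.n_negative])
    extra = [g for g in positive + negative if g not in activated]
    activated = sorted(set(activated) | set(extra))

    truth = {
        "predominant": predominant,
        "marrow_expressed": sorted(marrow_expressed),
        "silent": silent,
        "activated": activated,
        "positive": positive,
        "negative": negative,
    }
    return matrix, ann, truth


def simulate_cohort(cfg: SimConfig, truth: dict, size: int, stream: int = 1):
    """Generate one tumor cohort: expression, survival table, activation mask.

    Each activated gene is "on" in a Bernoulli(``activation_freq``) subset of
    patients (expression = baseline + activation_shift + noise) and at
    background elsewhere.  Survival times are exponential with hazard
    ``baseline_hazard`` times the product of the hazard multipliers of the
    patient's active planted genes, right-censored by an independent
    exponential at ``censor_rate``.  Clinical covariates are independent
    Bernoulli draws with the configured prevalences.
    """
    if size < 10:
        raise ValueError("cohort size must be >= 10 for the survival screen")
    rng = cfg.rng(stream)
    genes = [f"G{i:04d}" for i in range(cfg.n_genes)]
    gene_index = pd.Index(genes, name="gene_id")
    samples = [f"P{stream}_{i:04d}" for i in range(size)]

    activated = [g for g in truth["activated"] if g in set(genes)]
    mask = pd.DataFrame(False, index=gene_index, columns=samples)
    act_draw = rng.random((len(activated), size)) < cfg.activation_freq
    mask.loc[activated] = act_draw

    values = cfg.baseline_expr + _noise(rng, (cfg.n_genes, size), cfg.noise_sd, cfg.noise_clip)
    values = values + cfg.activation_shift * mask.to_numpy()
    matrix = pd.DataFrame(values, index=gene_index, columns=samples)

    log_hr = np.zeros(size)
    for g in truth["positive"]:
        log_hr += np.log(cfg.hr_positive) * mask.loc[g].to_numpy()
    for g in truth["negative"]:
        log_hr += np.log(cfg.hr_negative) * mask.loc[g].to_numpy()
    hazard = cfg.baseline_hazard * np.exp(log_hr)
    t_event = rng.exponential(1.0 / hazard)
    if cfg.censor_rate > 0:
        t_cens = rng.exponential(1.0 / cfg.censor_rate, size)
    else:
        t_cens = np.full(size, np.inf)
    time = np.minimum(t_event, t_cens)
    event = t_event <= t_cens

    surv = pd.DataFrame(
        {"time": time, "event": event},
        index=pd.Index(samples, name="sample_id"),
    )
    for name, freq in cfg.covariate_freqs.items():
        surv[name] = (rng.random(size) < freq).astype(int)
    return matrix, surv, mask


def simulate_bundle(cfg: SimConfig) -> SyntheticBundle:
    """Full bundle: compendium plus one cohort per entry of ``cohort_sizes``."""
    matrix, ann, truth = simulate_compendium(cfg)
    cohorts = [
        simulate_cohort(cfg, truth, size, stream=1 + i)
        for i, size in enumerate(cfg.cohort_sizes)
    ]
    return SyntheticBundle(compendium=matrix, annotation=ann, cohorts=cohorts, truth=truth)


# ---------------------------------------------------------------------------
# RT-qPCR Ct tables


def simulate_ct_table(
    cfg: SimConfig,
    n_patients: int = 16,
    contaminated: tuple = (),
    wide_duplicates: tuple = (),
    planted_ratios: pd.DataFrame | None = None,
    sample_offsets: bool = True,
):
    """Generate an RT-qPCR Ct table with a testis reference, 7 normal bone
    marrows, 3 cord bloods and ``n_patients`` patients.

    Cts are constructed so the published ratio formula recovers the planted
    testis-relative expression exactly: for gene g in sample s,

        Ct(g, s) = Ct(g, testis) - log2(ratio(g, s)) + delta_s

    with the per-sample offset ``delta_s`` applied to every gene including
    the four control genes (whose planted ratio is 1), so normalization by
    the control-gene mean cancels ``delta_s`` exactly.  With
    ``sample_offsets=False`` the offsets are zero and a planted ratio of 1
    reproduces the testis Cts verbatim.  Duplicates are
    ``Ct +- d/2`` with spread d < 0.5 (their mean is the exact Ct);
    ``wide_duplicates`` entries ``(sample_id, gene_id)`` get d = 0.8 instead.
    no-RT Cts are >= 36 unless ``(sample_id, gene_id)`` is listed in
    ``contaminated``, in which case Ct(noRT) = 34.

    Returns ``(records, truth)``; truth holds the planted ratio table and
    the expected boolean expression calls for prognostic/frequent genes.
    """
    rng = cfg.rng(100)
    prognostic = list(POSITIVE_GENES) + list(NEGATIVE_GENES)
    genes = prognostic + list(FREQUENT_GENES) + list(CONTROL_GENES)
    normals = [f"normal_bm_{i}" for i in range(7)] + [f"cord_blood_{i}" for i in range(3)]
    patients = [f"patient_{i:02d}" for i in range(n_patients)]
    samples = ["testis"] + normals + patients

    if planted_ratios is None:
        ratios = pd.DataFrame(1.0, index=pd.Index(samples, name="sample_id"), columns=genes)
        # normals: low but nonzero background, bounded away from patient
        # background so the mean+2SD threshold always separates them
        ratios.loc[normals, prognostic + list(FREQUENT_GENES)] = rng.uniform(
            0.01, 0.05, (len(normals), len(prognostic) + len(FREQUENT_GENES))
        )
        expressed = rng.random((n_patients, len(prognostic))) < 0.4
        pat_r = rng.uniform(0.001, 0.008, (n_patients, len(prognostic)))
        pat_r[expressed] = rng.uniform(0.5, 4.0, int(expressed.sum()))
        ratios.loc[patients, prognostic] = pat_r
        freq_on = rng.random((n_patients, len(FREQUENT_GENES))) < 0.8
        freq_r = rng.uniform(0.001, 0.008, (n_patients, len(FREQUENT_GENES)))
        freq_r[freq_on] = rng.uniform(0.5, 4.0, int(freq_on.sum()))
        ratios.loc[patients, list(FREQUENT_GENES)] = freq_r
    else:
        ratios = planted_ratios
        samples = list(ratios.index)
        patients = [s for s in samples if s not in normals and s != "testis"]

    ct_testis = pd.Series(rng.uniform(22, 27, len(genes)), index=genes)
    if sample_offsets:
        delta = pd.Series(rng.uniform(-1.5, 1.5, len(samples)), index=ratios.index)
    else:
        delta = pd.Series(0.0, index=ratios.index)
    delta["testis"] = 0.0

    rows = []
    for s in ratios.index:
        for g in genes:
            ct = ct_testis[g] - np.log2(ratios.loc[s, g]) + delta[s]
            d = 0.8 if (s, g) in set(wide_duplicates) else rng.uniform(0.0, 0.45)
            no_rt = 34.0 if (s, g) in set(contaminated) else 36.0 + rng.uniform(0.5, 3.0)
            role = (
                "control"
                if g in CONTROL_GENES
                else "frequent"
                if g in FREQUENT_GENES
                else "prognostic"
            )
            rows.append(
                {
                    "sample_id": s,
                    "gene_id": g,
                    "ct_dup1": ct + d / 2,
                    "ct_dup2": ct - d / 2,
                    "ct_noRT": no_rt,
                    "role": role,
                }
            )
    records = pd.DataFrame(rows)
    truth = {"ratios": ratios, "ct_testis": ct_testis, "delta": delta, "patients": patients, "normals": normals}
    return records, truth
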