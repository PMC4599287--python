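"""Readers and writers for the pipeline's interchange formats.

All tabular formats are UTF-8 TSV with a header row and '.' decimal
separator; expression matrices have genes as rows (first column the gene
id) and samples as columns.  Gene sets use the standard GMT format
(set name, description, members; tab-separated), parsed with gseapy.
Ct tables are CSV.  Synthetic-truth sidecars are JSON.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from gseapy.parser import read_gmt as _read_gmt


@dataclass
class PipelineConfig:
    """Fixed analysis constants plus input paths.

    The defaults carry the study's constants: 3 SD for array thresholds,
    2 SD for qPCR thresholds, the 10% aberrant-frequency filter, p < 0.05
    for the per-cohort screen, p < 0.01 for differential expression,
    p < 0.20 for the multivariate univariate screen, and top-3 selection
    per direction.
    """

    expression: str | None = None
    annotation: str | None = None
    survival: str | None = None
    gene_sets: str | None = None
    ct_table: str | None = None
    k_array: float = 3.0
    k_qpcr: float = 2.0
    min_freq: float = 0.10
    alpha_screen: float = 0.05
    alpha_de: float = 0.01
    screen_p_multivariate: float = 0.20
    n_top: int = 3
    n_perm: int = 999
    seed: int = 0
    survival_horizon: float | None = None

    def __post_init__(self):
        for name in ("min_freq", "alpha_screen", "alpha_de", "screen_p_multivariate"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if self.k_array <= 0 or self.k_qpcr <= 0:
            raise ValueError("SD multipliers must be > 0")


def read_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**data)


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "gene_id"
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique()
        raise ValueError(f"duplicate gene ids: {list(dupes)}")
    if df.isna().to_numpy().any():
        raise ValueError("expression matrix contains missing values")
    return df


def write_expression_tsv(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t")


def read_annotation_tsv(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    if not {"sample_id", "group"} <= set(df.columns):
        raise ValueError("annotation TSV needs columns: sample_id, group")
    return df.set_index("sample_id")["group"]


def write_annotation_tsv(ann: pd.Series, path: str | Path) -> None:
    ann.rename("group").rename_axis("sample_id").reset_index().to_csv(
        path, sep="\t", index=False
    )


def read_survival_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if not {"sample_id", "time", "event"} <= set(df.columns):
        raise ValueError("survival TSV needs columns: sample_id, time, event")
    df = df.set_index("sample_id")
    if (df["time"] < 0).any():
        raise ValueError("negative survival times")
    df["event"] = df["event"].astype(bool)
    return df


def write_survival_tsv(surv: pd.DataFrame, path: str | Path) -> None:
    out = surv.copy()
    out["event"] = out["event"].astype(int)
    out.rename_axis("sample_id").reset_index().to_csv(path, sep="\t", index=False)


def write_calls_tsv(calls: pd.DataFrame, path: str | Path) -> None:
    calls.astype(int).to_csv(path, sep="\t")


def read_calls_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0).astype(bool)


def write_thresholds_tsv(thresholds: pd.DataFrame, path: str | Path) -> None:
    thresholds.rename_axis("gene_id").reset_index().to_csv(path, sep="\t", index=False)


def read_thresholds_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t").set_index("gene_id")


def read_gmt(path: str | Path) -> dict:
    """Gene sets from a GMT file: {set_name: [gene ids]}."""
    return _read_gmt(str(path))


def read_ct_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"sample_id", "gene_id", "ct_dup1", "ct_dup2", "ct_noRT", "role"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"Ct CSV missing columns: {sorted(missing)}")
    if (df[["ct_dup1", "ct_dup2"]] <= 0).to_numpy().any():
        raise ValueError("Ct values must be positive")
    if df[["ct_dup1", "ct_dup2"]].isna().to_numpy().any():
        raise ValueError("both duplicate Cts must be present")
    return df


def write_ct_csv(records: pd.DataFrame, path: str | Path) -> None:
    records.to_csv(path, index=False)


class _JSONEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, (set, tuple)):
            return sorted(o) if isinstance(o, set) else list(o)
        if isinstance(o, pd.Series):
            return o.to_dict()
        if isinstance(o, pd.DataFrame):
            return o.to_dict()
        return super().default(o)


def write_truth_json(truth: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, cls=_JSONEncoder, indent=1, sort_keys=True)


def read_truth_json(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
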