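"""Shared data containers and TSV input/output.

All matrices are oriented samples-in-rows, features-in-columns, with sample
IDs on the index and feature IDs on the columns.  Missing entries are NaN.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

OMIC_TAGS = ("rna", "mirna", "methylation")


@dataclass
class OmicsMatrix:
    """One omics block: a samples x features matrix with a missingness mask.

    Parameters
    ----------
    values : pd.DataFrame
        Real-valued grid; NaN marks a missing entry.  Index = sample IDs,
        columns = feature IDs, both unique.
    omic : str
        One of ``rna``, ``mirna``, ``methylation``.
    """

    values: pd.DataFrame
    omic: str

    def __post_init__(self) -> None:
        if self.omic not in OMIC_TAGS:
            raise ValueError(f"unknown omic tag {self.omic!r}; expected one of {OMIC_TAGS}")
        if self.values.index.has_duplicates:
            raise ValueError("duplicate sample IDs")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate feature IDs")
        self.values = self.values.astype(float)
        if self.omic == "methylation":
            arr = self.values.to_numpy()
            observed = arr[~np.isnan(arr)]
            if observed.size and (observed.min() < 0 or observed.max() > 1):
                raise ValueError("methylation beta values must lie in [0, 1]")

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.index

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()

    def is_complete(self) -> bool:
        return not bool(self.values.isna().to_numpy().any())

    def to_tsv(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t", index_label="sample_id")

    @classmethod
    def from_tsv(cls, path: str | Path, omic: str) -> "OmicsMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(values=df, omic=omic)


@dataclass
class StackedMatrix:
    """Column-wise concatenation of the omics blocks, complete and rescaled.

    ``block_of_origin`` maps each stacked feature ID to the omic block it
    came from.
    """

    values: pd.DataFrame
    block_of_origin: pd.Series

    def __post_init__(self) -> None:
        if self.values.isna().to_numpy().any():
            raise ValueError("stacked matrix must be complete (no missing values)")
        if not self.values.columns.equals(self.block_of_origin.index):
            raise ValueError("block_of_origin must be indexed by the stacked feature IDs")

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.index

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_tsv(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t", index_label="sample_id")


@dataclass
class ClinicalTable:
    """Per-sample overall survival time, event flag and optional covariates.

    ``data`` is indexed by sample ID and holds at least columns ``os_time``
    (non-negative, in years) and ``os_event`` (1 = death observed,
    0 = right-censored).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ("os_time", "os_event"):
            if col not in self.data.columns:
                raise ValueError(f"clinical table missing required column {col!r}")
        if self.data.index.has_duplicates:
            raise ValueError("duplicate sample IDs in clinical table")
        times = self.data["os_time"].to_numpy(dtype=float)
        if np.any(times < 0) or np.any(~np.isfinite(times)):
            raise ValueError("survival times must be finite and non-negative")
        events = self.data["os_event"].to_numpy()
        if not np.isin(events, [0, 1]).all():
            raise ValueError("event flag must be binary (0/1)")

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.index

    @property
    def time(self) -> pd.Series:
        return self.data["os_time"].astype(float)

    @property
    def event(self) -> pd.Series:
        return self.data["os_event"].astype(int)

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def subset(self, sample_ids: Sequence) -> "ClinicalTable":
        return ClinicalTable(self.data.loc[list(sample_ids)])

    def to_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index_label="sample_id")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ClinicalTable":
        return cls(pd.read_csv(path, sep="\t", index_col="sample_id"))


@dataclass
class RiskLabels:
    """Per-sample risk-group assignment with a recorded risk orientation.

    ``labels`` maps sample ID -> group tag (strings, e.g. ``G1``/``G2``).
    ``risk_order`` lists the group tags from best to worst survival, so the
    last entry is the higher-risk group.  By convention groups are named so
    that G1 has the better Kaplan-Meier survival.
    """

    labels: pd.Series
    risk_order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = self.labels.astype(str)
        groups = set(self.labels.unique())
        if self.risk_order and set(self.risk_order) != groups:
            raise ValueError("risk_order must name exactly the groups present in labels")

    @property
    def groups(self) -> list[str]:
        return sorted(self.labels.unique())

    @property
    def n_groups(self) -> int:
        return self.labels.nunique()

    @property
    def higher_risk(self) -> str:
        if not self.risk_order:
            raise ValueError("risk orientation not recorded for these labels")
        return self.risk_order[-1]

    def risk_score(self) -> pd.Series:
        """Numeric risk score per sample: the rank of its group in risk_order.

        For two groups this is the indicator of the higher-risk group.
        """
        if not self.risk_order:
            raise ValueError("risk orientation not recorded for these labels")
        rank = {g: i for i, g in enumerate(self.risk_order)}
        return self.labels.map(rank).astype(float)

    def subset(self, sample_ids: Sequence) -> "RiskLabels":
        sub = self.labels.loc[list(sample_ids)]
        present = set(sub.unique())
        order = [g for g in self.risk_order if g in present]
        return RiskLabels(labels=sub, risk_order=order)

    def to_tsv(self, path: str | Path) -> None:
        out = self.labels.rename("group").to_frame()
        out.to_csv(path, sep="\t", index_label="sample_id")

    @classmethod
    def from_tsv(cls, path: str | Path, risk_order: Sequence[str] = ()) -> "RiskLabels":
        df = pd.read_csv(path, sep="\t", index_col="sample_id")
        return cls(labels=df["group"], risk_order=list(risk_order))


@dataclass
class EvalReport:
    """Survival-separation metrics for one labeled cohort."""

    logrank_stat: float
    logrank_p: float
    c_index: float
    brier: float
    brier_horizon: float
    n_samples: int
    n_events: int

    def to_dict(self) -> dict:
        return {
            "logrank_stat": float(self.logrank_stat),
            "logrank_p": float(self.logrank_p),
            "c_index": float(self.c_index),
            "brier": float(self.brier),
            "brier_horizon": float(self.brier_horizon),
            "n_samples": int(self.n_samples),
            "n_events": int(self.n_events),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def align_samples(*objs: OmicsMatrix | ClinicalTable) -> list:
    """Restrict every object to the (ordered) intersection of sample IDs."""
    common: pd.Index | None = None
    for o in objs:
        ids = o.sample_ids
        common = ids if common is None else common.intersection(ids)
    if common is None or len(common) == 0:
        raise ValueError("sample intersection is empty")
    out = []
    for o in objs:
        if isinstance(o, OmicsMatrix):
            out.append(OmicsMatrix(values=o.values.loc[common], omic=o.omic))
        else:
            out.append(o.subset(common))
    return out
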