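"""Longitudinal cohort container and per-subject DPS time warps.

A cohort is a long-format table: one row per (subject, visit, biomarker)
observation with the subject's age at that visit and diagnostic group
(CN / LMCI / AD).  Biomarkers are coded A (CSF amyloid-beta 1-42),
T (CSF total tau), N (hippocampal-volume ratio) and C (ADAS-13); on the
normalized latent scale all four start near 0 and grow with disease.

The disease progression score (DPS) maps each subject's age onto a common
disease-time axis through a per-subject affine warp s_i(t) = alpha_i*t +
beta_i, where alpha_i is the progression rate and beta_i the onset offset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .model import BIOMARKERS

__all__ = ["COLUMNS", "CohortTable", "DpsParams", "CohortValidationError"]

COLUMNS = ("subject_id", "visit", "age_years", "group", "biomarker", "value")
GROUPS = ("CN", "LMCI", "AD")

# loose guard for noise around the [0, 1] latent scale
_NORM_LO, _NORM_HI = -0.5, 1.5


class CohortValidationError(ValueError):
    pass


@dataclass
class CohortTable:
    """Validated long-format biomarker table.

    ``scale`` is 'normalized' (latent [0, 1]-ish scale the model works on)
    or 'clinical' (original units); the latent-range guard only applies to
    normalized tables.
    """

    df: pd.DataFrame
    scale: str = "normalized"

    def __post_init__(self):
        df = self.df
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise CohortValidationError(f"missing columns: {missing}")
        df = df.loc[:, list(COLUMNS)].copy()
        df["subject_id"] = df["subject_id"].astype(str)
        df["visit"] = df["visit"].astype(int)
        for col in ("age_years", "value"):
            vals = pd.to_numeric(df[col], errors="coerce")
            bad = df.index[vals.isna() & df[col].notna()]
            if len(bad):
                raise CohortValidationError(f"non-numeric {col} at rows {list(bad[:5])}")
            df[col] = vals
        if df["value"].isna().any():
            df = df[df["value"].notna()]
        unknown = set(df["biomarker"]) - set(BIOMARKERS)
        if unknown:
            raise CohortValidationError(f"unknown biomarker codes: {sorted(unknown)}")
        badg = set(df["group"]) - set(GROUPS)
        if badg:
            raise CohortValidationError(f"unknown diagnostic groups: {sorted(badg)}")
        dup = df.duplicated(subset=["subject_id", "visit", "biomarker"])
        if dup.any():
            raise CohortValidationError(
                f"duplicate (subject, visit, biomarker) rows: {list(df.index[dup][:5])}")
        if not np.all(np.isfinite(df["age_years"])) or (df["age_years"] <= 0).any():
            raise CohortValidationError("ages must be positive and finite")
        # one age per (subject, visit), strictly increasing across visits
        per_visit = df.groupby(["subject_id", "visit"])["age_years"]
        if (per_visit.nunique() > 1).any():
            raise CohortValidationError("inconsistent age within a (subject, visit)")
        ages = df.drop_duplicates(["subject_id", "visit"]).sort_values(
            ["subject_id", "visit"])
        for sid, grp in ages.groupby("subject_id"):
            a = grp["age_years"].to_numpy()
            if np.any(np.diff(a) <= 0):
                raise CohortValidationError(
                    f"ages not strictly increasing across visits for subject {sid}")
        if self.scale == "normalized":
            v = df["value"].to_numpy()
            if np.any(v < _NORM_LO) or np.any(v > _NORM_HI):
                raise CohortValidationError(
                    f"normalized values outside [{_NORM_LO}, {_NORM_HI}]")
        self.df = df.sort_values(["subject_id", "visit", "biomarker"]).reset_index(drop=True)

    # -- index helpers ------------------------------------------------------
    @property
    def subjects(self) -> list[str]:
        return sorted(self.df["subject_id"].unique())

    @property
    def n_subjects(self) -> int:
        return self.df["subject_id"].nunique()

    def observations(self, k: str) -> pd.DataFrame:
        """All rows for biomarker k (the index set I_k)."""
        return self.df[self.df["biomarker"] == k]

    def subject(self, subject_id: str) -> pd.DataFrame:
        """All rows for one subject (the index set I_i)."""
        return self.df[self.df["subject_id"] == str(subject_id)]

    def subject_group(self, subject_id: str) -> str:
        return str(self.subject(subject_id)["group"].iloc[0])

    def subset_groups(self, groups: Iterable[str]) -> "CohortTable":
        groups = set(groups)
        return CohortTable(self.df[self.df["group"].isin(groups)].copy(), scale=self.scale)

    def summary(self) -> pd.DataFrame:
        """Per-group subject / visit / observation counts."""
        g = self.df.drop_duplicates(["subject_id"]).groupby("group")["subject_id"].count()
        v = self.df.drop_duplicates(["subject_id", "visit"]).groupby("group")["visit"].count()
        o = self.df.groupby("group")["value"].count()
        return pd.DataFrame({"subjects": g, "visits": v, "observations": o}).fillna(0).astype(int)

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)


@dataclass
class DpsParams:
    """Per-subject linear age->DPS warps: s_i(t) = alpha_i * t + beta_i."""

    alpha: dict[str, float] = field(default_factory=dict)
    beta: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if set(self.alpha) != set(self.beta):
            raise ValueError("alpha and beta must cover the same subjects")
        self.alpha = {str(k): float(v) for k, v in self.alpha.items()}
        self.beta = {str(k): float(v) for k, v in self.beta.items()}

    def s(self, subject_id: str, ages) -> np.ndarray:
        sid = str(subject_id)
        return self.alpha[sid] * np.asarray(ages, dtype=float) + self.beta[sid]

    def __contains__(self, subject_id) -> bool:
        return str(subject_id) in self.alpha

    def subjects(self) -> list[str]:
        return sorted(self.alpha)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "subject_id": self.subjects(),
            "alpha": [self.alpha[s] for s in self.subjects()],
            "beta": [self.beta[s] for s in self.subjects()],
        })

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "DpsParams":
        return cls(alpha=dict(zip(df["subject_id"].astype(str), df["alpha"])),
                   beta=dict(zip(df["subject_id"].astype(str), df["beta"])))

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "DpsParams":
        return cls.from_dataframe(pd.read_csv(path))
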