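"""Synthetic longitudinal cohorts with known ground truth.

Emulates the structure of a multicenter AD biomarker study: three diagnostic
groups whose baseline disease-progression scores are ordered CN < LMCI < AD,
per-subject linear age->DPS warps, latent trajectories from the cascade ODE,
irregular visit schedules, additive Gaussian observation noise on the
normalized scale, and independent per-(visit, biomarker) missingness.
Subjects ending up with fewer than two observations of any biomarker are
dropped, mirroring the eligibility rule applied to the real cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import CohortTable, DpsParams
from .model import BIOMARKERS, CascadeParams, S_MAX, S_MIN, _dense_solution, load_fixture_params

__all__ = ["GeneratorConfig", "TruthBundle", "generate_cohort", "to_clinical_scale",
           "DEFAULT_CLINICAL_ANCHORS"]

#: reference-cohort group-mean anchors in clinical units: (value at latent 0,
#: value at latent 1, flips with disease).  CSF amyloid-beta 1-42 and
#: hippocampal volume decrease with disease; total tau and ADAS-13 increase.
DEFAULT_CLINICAL_ANCHORS = {
    "A": {"healthy": 201.74, "diseased": 139.79},   # pg/ml
    "T": {"healthy": 72.69, "diseased": 122.01},    # pg/ml
    "N": {"healthy": 7045.38, "diseased": 5488.95}, # mm^3-scale volume
    "C": {"healthy": 10.29, "diseased": 32.49},     # ADAS-13 points
}

_GROUP_DPS = {"CN": (-4.0, 2.0), "LMCI": (0.5, 1.5), "AD": (5.0, 2.0)}


@dataclass
class GeneratorConfig:
    """Study-design knobs for the synthetic cohort.

    Defaults follow the emulated study: group mix ~ 229/398/192, baseline
    age 75 +- 7 years truncated to [55, 90], progression rates alpha uniform
    on (0.5, 2.0), 2-6 visits spaced 0.5-1.5 years apart, observation noise
    SD 0.03 on the normalized scale, and group-specific baseline DPS
    (CN < 0, LMCI near 0, AD > 0).
    """

    seed: int
    n_subjects: int = 100
    group_fracs: tuple[float, float, float] = (0.28, 0.49, 0.23)  # CN, LMCI, AD
    truth: CascadeParams | None = None
    alpha_range: tuple[float, float] = (0.5, 2.0)
    age_mean: float = 75.0
    age_sd: float = 7.0
    age_bounds: tuple[float, float] = (55.0, 90.0)
    visits_range: tuple[int, int] = (2, 6)
    spacing_range: tuple[float, float] = (0.5, 1.5)
    noise_sd: dict[str, float] = field(default_factory=lambda: {k: 0.03 for k in BIOMARKERS})
    missing_prob: dict[str, float] = field(default_factory=lambda: {k: 0.0 for k in BIOMARKERS})

    def validate(self) -> None:
        errs = []
        if abs(sum(self.group_fracs) - 1.0) > 1e-9:
            errs.append("group_fracs must sum to 1")
        if any(v < 0 for v in self.noise_sd.values()):
            errs.append("noise_sd entries must be >= 0")
        if any(not (0 <= v <= 1) for v in self.missing_prob.values()):
            errs.append("missing_prob entries must lie in [0, 1]")
        if self.n_subjects < 1:
            errs.append("n_subjects must be >= 1")
        if not (self.alpha_range[0] > 0 and self.alpha_range[1] <= 4):
            errs.append("alpha_range must lie in (0, 4]")
        if self.visits_range[0] < 2:
            errs.append("visits_range must start at >= 2")
        if errs:
            raise ValueError("invalid generator config: " + "; ".join(errs))


@dataclass
class TruthBundle:
    params: CascadeParams
    dps: DpsParams
    latent: pd.DataFrame  # subject_id, visit, s, biomarker, value (noise-free)


def generate_cohort(config: GeneratorConfig) -> tuple[CohortTable, TruthBundle]:
    """Draw a cohort and return it with its full generating truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    truth = config.truth if config.truth is not None else load_fixture_params("lmci_ad")
    sol = _dense_solution(truth)

    groups = rng.choice(["CN", "LMCI", "AD"], size=config.n_subjects, p=config.group_fracs)
    rows, latent_rows = [], []
    alpha_map, beta_map = {}, {}
    for idx in range(config.n_subjects):
        sid = f"S{idx + 1:04d}"
        group = groups[idx]
        # baseline age, truncated normal by resampling
        while True:
            t0 = rng.normal(config.age_mean, config.age_sd)
            if config.age_bounds[0] <= t0 <= config.age_bounds[1]:
                break
        n_visits = int(rng.integers(config.visits_range[0], config.visits_range[1] + 1))
        gaps = rng.uniform(*config.spacing_range, size=n_visits - 1)
        ages = t0 + np.concatenate([[0.0], np.cumsum(gaps)])
        alpha = rng.uniform(*config.alpha_range)
        mu, sd = _GROUP_DPS[group]
        span = alpha * (ages[-1] - ages[0])
        # baseline DPS from the group distribution, kept so every visit's DPS
        # stays inside the model domain
        while True:
            s_base = rng.normal(mu, sd)
            if S_MIN <= s_base <= S_MAX - span:
                break
        beta = s_base - alpha * ages[0]
        alpha_map[sid], beta_map[sid] = float(alpha), float(beta)
        s = alpha * ages + beta
        latent = sol(s)  # (4, n_visits)
        keep_subject = True
        sub_rows, sub_latent = [], []
        for ki, k in enumerate(BIOMARKERS):
            noise = rng.normal(0.0, config.noise_sd[k], size=n_visits)
            miss = rng.random(n_visits) < config.missing_prob[k]
            if (~miss).sum() < 2:
                keep_subject = False
            for j in range(n_visits):
                sub_latent.append((sid, j + 1, float(s[j]), k, float(latent[ki, j])))
                if miss[j]:
                    continue
                sub_rows.append((sid, j + 1, float(ages[j]), group, k,
                                 float(latent[ki, j] + noise[j])))
        if not keep_subject:  # fewer than two measurements of some biomarker
            del alpha_map[sid], beta_map[sid]
            continue
        rows.extend(sub_rows)
        latent_rows.extend(sub_latent)

    df = pd.DataFrame(rows, columns=["subject_id", "visit", "age_years",
                                     "group", "biomarker", "value"])
    cohort = CohortTable(df, scale="normalized")
    bundle = TruthBundle(
        params=truth,
        dps=DpsParams(alpha=alpha_map, beta=beta_map),
        latent=pd.DataFrame(latent_rows, columns=["subject_id", "visit", "s",
                                                  "biomarker", "value"]))
    return cohort, bundle


def to_clinical_scale(cohort: CohortTable, anchors: dict | None = None) -> CohortTable:
    """Map normalized latent values to clinical units per biomarker.

    Each biomarker maps affinely between its 'healthy' anchor (latent 0) and
    'diseased' anchor (latent 1); biomarkers whose clinical value falls with
    disease (amyloid, hippocampal volume) get the orientation flip
    automatically because their diseased anchor is below the healthy one.
    Exact inverse of pipeline_io.normalize_cohort with the same anchors.
    """
    anchors = DEFAULT_CLINICAL_ANCHORS if anchors is None else anchors
    missing = [k for k in set(cohort.df["biomarker"]) if k not in anchors]
    if missing:
        raise KeyError(f"no clinical anchors for biomarkers: {sorted(missing)}")
    df = cohort.df.copy()
    for k, spec in anchors.items():
        m = df["biomarker"] == k
        h, d = float(spec["healthy"]), float(spec["diseased"])
        df.loc[m, "value"] = h + (d - h) * df.loc[m, "value"]
    return CohortTable(df, scale="clinical")
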