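"""Cohort readers, normalization/orientation, and the end-to-end pipeline.

The canonical input is a long-format CSV (subject_id, age_years, group,
biomarker, value, optional visit); a wide-format convenience reader accepts
one column per biomarker with study-export-style headers.  Normalization
maps clinical units onto the latent [0, 1]-ish scale the cascade model works
on, flipping biomarkers whose clinical value falls as disease progresses
(CSF amyloid-beta, hippocampal volume).
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .calibration import calibrate
from .cohort import CohortTable, DpsParams
from .discovery import discover_model
from .model import BIOMARKERS, load_fixture_params
from .personalize import cohort_personalization_report
from .sensitivity import make_ranges, select_personalized, sobol_indices
from .sigmoid import fit_sigmoid
from .synthetic import DEFAULT_CLINICAL_ANCHORS, GeneratorConfig, generate_cohort

__all__ = ["OrientationSpec", "read_cohort", "normalize_cohort", "run_pipeline",
           "population_sigmoids"]

#: wide-format column headers accepted for each biomarker
WIDE_HEADERS = {
    "A": ("A", "ABETA", "CSF_ABETA42"),
    "T": ("T", "TAU", "CSF_TTAU"),
    "N": ("N", "HIPP", "HIPPOCAMPUS", "HIPPV"),
    "C": ("C", "ADAS13", "ADAS"),
}


@dataclass(frozen=True)
class OrientationSpec:
    """Per-biomarker normalization anchors and disease-orientation flags.

    ``anchors[k] = (low, high)`` are clinical reference values; normalization
    is x = (v - low) / (high - low), followed by x -> 1 - x when
    ``flip[k]`` is set (biomarkers that decrease with disease).
    """

    anchors: dict[str, tuple[float, float]]
    flip: dict[str, bool]

    def __post_init__(self):
        for k, (lo, hi) in self.anchors.items():
            if lo == hi:
                raise ValueError(f"degenerate anchors for biomarker {k}: low == high")

    @classmethod
    def reference_means(cls) -> "OrientationSpec":
        """Preset anchored at the reference cohort's CN and AD group means."""
        anchors, flip = {}, {}
        for k, spec in DEFAULT_CLINICAL_ANCHORS.items():
            h, d = spec["healthy"], spec["diseased"]
            anchors[k] = (min(h, d), max(h, d))
            flip[k] = d < h
        return cls(anchors=anchors, flip=flip)

    @classmethod
    def from_cohort(cls, cohort: CohortTable,
                    quantiles: tuple[float, float] = (0.025, 0.975)) -> "OrientationSpec":
        """Robust per-biomarker anchors from cohort percentiles, with the
        standard clinical orientation flags.

        If a biomarker's tails are long relative to its central range (so
        percentile anchors would map extremes outside the latent guard
        band), the anchors widen to the observed min/max with a 2% margin.
        """
        ref = cls.reference_means()
        anchors = {}
        for k in BIOMARKERS:
            v = cohort.observations(k)["value"]
            if v.empty:
                continue
            lo, hi = float(v.quantile(quantiles[0])), float(v.quantile(quantiles[1]))
            if lo == hi:
                raise ValueError(f"degenerate anchor percentiles for biomarker {k}")
            vmin, vmax = float(v.min()), float(v.max())
            if (vmin - lo) / (hi - lo) < -0.45 or (vmax - lo) / (hi - lo) > 1.45:
                pad = 0.02 * (vmax - vmin)
                lo, hi = vmin - pad, vmax + pad
            anchors[k] = (lo, hi)
        return cls(anchors=anchors, flip={k: ref.flip[k] for k in anchors})


def read_cohort(path, dialect: str = "long") -> CohortTable:
    """Read a clinical-units cohort CSV (long or wide layout)."""
    df = pd.read_csv(path)
    if dialect == "wide":
        id_cols = [c for c in ("subject_id", "visit", "age_years", "group") if c in df.columns]
        missing = [c for c in ("subject_id", "age_years", "group") if c not in df.columns]
        if missing:
            raise ValueError(f"wide cohort file missing columns: {missing}")
        colmap = {}
        for k, names in WIDE_HEADERS.items():
            for name in names:
                if name in df.columns:
                    colmap[name] = k
                    break
        if not colmap:
            raise ValueError("wide cohort file has no recognizable biomarker columns")
        df = df.melt(id_vars=id_cols, value_vars=list(colmap),
                     var_name="biomarker", value_name="value")
        df["biomarker"] = df["biomarker"].map(colmap)
        df = df[df["value"].notna()]
    elif dialect != "long":
        raise ValueError(f"unknown dialect {dialect!r}")
    required = ["subject_id", "age_years", "group", "biomarker", "value"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"cohort file missing columns: {missing}")
    if "visit" not in df.columns:
        ranks = df.groupby("subject_id")["age_years"].rank(method="dense")
        df = df.assign(visit=ranks.astype(int))
    return CohortTable(df, scale="clinical")


def normalize_cohort(cohort: CohortTable, spec: OrientationSpec | None = None) -> CohortTable:
    """Clinical units -> normalized latent scale (inverse of to_clinical_scale
    when the same anchors are used); defaults to robust cohort percentiles."""
    if spec is None:
        spec = OrientationSpec.from_cohort(cohort)
    df = cohort.df.copy()
    for k in sorted(set(df["biomarker"])):
        if k not in spec.anchors:
            raise KeyError(f"no anchors for biomarker {k}")
        lo, hi = spec.anchors[k]
        m = df["biomarker"] == k
        x = (df.loc[m, "value"] - lo) / (hi - lo)
        df.loc[m, "value"] = 1.0 - x if spec.flip.get(k, False) else x
    return CohortTable(df, scale="normalized")


def population_sigmoids(cohort: CohortTable, dps: DpsParams) -> dict:
    """Population-level sigmoid fits: pool every subject's (s, y) points per
    biomarker and fit one four-parameter sigmoid each."""
    sigmoids = {}
    for k in BIOMARKERS:
        obs = cohort.observations(k)
        s = np.concatenate([dps.s(sid, g["age_years"].to_numpy())
                            for sid, g in obs.groupby("subject_id")])
        y = np.concatenate([g["value"].to_numpy() for _, g in obs.groupby("subject_id")])
        sigmoids[k] = fit_sigmoid((s, y)).params
    return sigmoids


def run_pipeline(config: dict, outdir, seed: int = 0) -> dict:
    """Execute the full analysis chain and write per-stage artifacts.

    Stages: simulate (or load+normalize) -> calibrate -> fit-sigmoid ->
    discover -> sensitivity -> personalize.  Returns the run manifest, also
    written as manifest.json in ``outdir``.  Any stage error aborts with the
    stage name; artifacts of completed stages are preserved.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    stage_seeds = {name: int(rng.integers(0, 2 ** 31 - 1))
                   for name in ("simulate", "calibrate", "sensitivity")}
    manifest = {"seed": seed, "stage_seeds": stage_seeds, "stages": [], "config": config}

    def record(name, t0, **info):
        manifest["stages"].append({"name": name, "seconds": round(time.time() - t0, 3), **info})

    try:
        # ---- stage 1: cohort -------------------------------------------------
        t0 = time.time()
        if "cohort_csv" in config:
            cohort = read_cohort(config["cohort_csv"], config.get("dialect", "long"))
            cohort = normalize_cohort(cohort)
        else:
            sim = config.get("simulate", {})
            gen = GeneratorConfig(seed=stage_seeds["simulate"], **sim)
            cohort, bundle = generate_cohort(gen)
            bundle.params.to_json(outdir / "truth_params.json")
            bundle.dps.to_csv(outdir / "truth_dps.csv")
        cohort.to_csv(outdir / "cohort_normalized.csv")
        record("simulate", t0, subjects=cohort.n_subjects)

        # ---- stage 2: population calibration --------------------------------
        t0 = time.time()
        state = calibrate(cohort, L=config.get("calibration_rounds", 10),
                          polish=config.get("calibration_polish", True),
                          multi_start=config.get("calibration_multi_start", True),
                          seed=stage_seeds["calibrate"])
        state.w.to_json(outdir / "population_params.json")
        state.dps.to_csv(outdir / "dps.csv")
        pd.DataFrame({"round": range(1, len(state.history) + 1),
                      "objective": state.history}).to_csv(
            outdir / "objective_history.csv", index=False)
        record("calibrate", t0, objective=state.objective, rounds=state.iteration)

        # ---- stage 3: population sigmoid fits --------------------------------
        t0 = time.time()
        sigmoids = population_sigmoids(cohort, state.dps)
        with open(outdir / "sigmoids.json", "w") as fh:
            json.dump({k: th.to_dict() for k, th in sigmoids.items()}, fh, indent=1)
        record("fit-sigmoid", t0)

        # ---- stage 4: sparse structure discovery -----------------------------
        t0 = time.time()
        disc = discover_model(sigmoids, m_max=config.get("m_max", 4),
                              lam=config.get("lasso_lambda", 1e-7))
        (outdir / "discovery_report.txt").write_text(disc.report() + "\n")
        if disc.params is not None:
            disc.params.to_json(outdir / "discovered_params.json")
        record("discover", t0, m_star=disc.m_star)

        # ---- stage 5: Sobol sensitivity --------------------------------------
        t0 = time.time()
        # the sensitivity analysis defaults to the freshly calibrated
        # weights; a fixture name or parameter file can be named instead
        sens_src = config.get("sensitivity_params")
        if sens_src is None:
            sens_params = state.w
        elif Path(str(sens_src)).exists():
            from .model import CascadeParams
            sens_params = CascadeParams.from_json(sens_src)
        else:
            sens_params = load_fixture_params(str(sens_src))
        ranges = make_ranges(sens_params)
        res = sobol_indices(ranges, output=("C", config.get("sensitivity_s", 0.0)),
                            N=config.get("sobol_n", 2 ** 13),
                            seed=stage_seeds["sensitivity"])
        pd.DataFrame({"parameter": res.names, "S1": res.S1, "S1_se": res.S1_se,
                      "ST": res.ST, "ST_se": res.ST_se}).to_csv(
            outdir / "sobol_indices.csv", index=False)
        sensitive = select_personalized(res, tol=config.get("sensitivity_tol", 0.01))
        record("sensitivity", t0, selected=sensitive)

        # ---- stage 6: personalization ----------------------------------------
        t0 = time.time()
        per_subject, summary = cohort_personalization_report(
            cohort, state.w, sensitive, state.dps)
        per_subject.to_csv(outdir / "personalization.csv", index=False)
        summary.to_csv(outdir / "personalization_summary.csv", index=False)
        record("personalize", t0, eligible=len(per_subject))
    except Exception as exc:
        manifest["error"] = {"stage": len(manifest["stages"]) + 1, "message": str(exc)}
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, default=str)
        raise
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest
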