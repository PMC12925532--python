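"""End-to-end orchestration: masks -> features -> cohort -> pooled
women-vs-men results, plus the two sensitivity analyses and the
rupture-prone direction annotation.

The main product is a tidy results table with one row per
(outcome × model family × adjustment), mirroring the reporting layout:
four global parameters as linear models on transformed, Z-standardized
outcomes; two local parameters as logistic models on median-dichotomized
outcomes; and exploratory continuous linear models for the local
parameters.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import stats as st
from .cohort import (
    LOCATION_ANALYSIS_MAP,
    complete_cases,
    select_index_aneurysm,
    validate_cohort,
)
from .errors import SchemaError
from .morphometry import MorphometryConfig, analyze_mask, records_to_frame

log = logging.getLogger(__name__)

#: outcome -> (model family, transform) for the primary analysis.
PRIMARY_MODELS = {
    "volume": ("linear", "log"),
    "sphericity": ("linear", "identity"),
    "elongation": ("linear", "boxcox"),
    "flatness": ("linear", "identity"),
    "shape_index": ("logistic", "dichotomize"),
    "curvedness": ("logistic", "dichotomize"),
}
#: exploratory continuous models for the local parameters.
EXPLORATORY_MODELS = {
    "shape_index": ("linear", "identity"),
    "curvedness": ("linear", "identity"),
}

#: rupture-prone coding: True when *higher* values mark rupture-prone shape.
RUPTURE_PRONE_HIGH = {
    "volume": True,
    "sphericity": False,
    "elongation": False,
    "flatness": False,
    "shape_index": False,
    "curvedness": True,
}

FULL_ADJUSTMENT = ("age", "hypertension", "smoking_ever", "size_mm", "location", "modality")


@dataclass(frozen=True)
class AnalysisConfig:
    """Configuration of the women-vs-men comparison."""

    adjustment: tuple = FULL_ADJUSTMENT
    m: int = 15
    iterations: int = 30
    seed: int = 0
    drop_smoking: bool = False
    complete_case: bool = False
    exploratory_continuous: bool = True
    morphometry: MorphometryConfig = field(default_factory=MorphometryConfig)


@dataclass
class ResultsTable:
    """Tidy results plus the run manifest."""

    table: pd.DataFrame
    manifest: dict

    def write(self, out_dir: str | Path, stem: str = "results") -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.table.to_csv(out_dir / f"{stem}.csv", index=False)
        with open(out_dir / f"{stem}_manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2, default=str)


# ---------------------------------------------------------------------------
# Feature batch
# ---------------------------------------------------------------------------

def run_morphometry_batch(
    mask_dir: str | Path,
    config: MorphometryConfig | None = None,
    out_csv: str | Path | None = None,
):
    """One MorphologyRecord row per readable NIfTI mask in ``mask_dir``.

    Unreadable or failing files are logged and skipped; the batch
    continues.  Returns ``(frame, failures)``.
    """
    from .meshing import load_nifti_mask

    cfg = config or MorphometryConfig()
    records, failures = {}, {}
    paths = sorted(
        p for p in Path(mask_dir).iterdir()
        if p.name.endswith((".nii", ".nii.gz"))
    )
    for path in paths:
        key = path.name.removesuffix(".gz").removesuffix(".nii")
        try:
            mask = load_nifti_mask(path)
            records[key] = analyze_mask(mask, cfg)
        except Exception as exc:  # noqa: BLE001 - batch must continue
            log.error("morphometry failed for %s: %s", path.name, exc)
            failures[key] = str(exc)
    frame = records_to_frame(records) if records else None
    if out_csv is not None and frame is not None:
        frame.to_csv(out_csv)
    return frame, failures


# ---------------------------------------------------------------------------
# Analysis table preparation
# ---------------------------------------------------------------------------

def prepare_analysis_table(cohort: pd.DataFrame) -> pd.DataFrame:
    """Index-aneurysm selection plus analysis recodes.

    Adds: ``woman`` indicator (men = reference), ``smoking_ever``
    (current/former combined vs never; NaN preserved) and
    ``location_analysis`` (posterior communicating + posterior circulation
    combined into one of 4 categories).
    """
    validate_cohort(cohort)
    df = select_index_aneurysm(cohort).copy()
    if set(df["sex"]) != {"woman", "man"}:
        raise SchemaError("both sexes must be present in the cohort")
    df["woman"] = (df["sex"] == "woman").astype(int)
    df["smoking_ever"] = df["smoking"].map(
        {"current": 1.0, "former": 1.0, "never": 0.0}
    )
    df["location_analysis"] = df["location"].map(LOCATION_ANALYSIS_MAP)
    return df


def build_design(
    df: pd.DataFrame, adjustment: tuple, drop: tuple = ()
) -> pd.DataFrame:
    """Design matrix: woman indicator plus dummy-coded adjustment set.

    Reference levels: men, MCA location, CTA modality, never-smoker.
    """
    cols = {"woman": df["woman"].astype(float)}
    for term in adjustment:
        if term in drop:
            continue
        if term == "location":
            loc = pd.Categorical(
                df["location_analysis"],
                categories=["mca", "aca_acom", "ica", "pcom_posterior"],
            )
            dummies = pd.get_dummies(loc, prefix="loc", drop_first=True, dtype=float)
            for c in dummies.columns:
                cols[c] = dummies[c].to_numpy()
        elif term == "modality":
            cols["mra"] = (df["modality"] == "mra").astype(float)
        else:
            cols[term] = df[term].astype(float)
    return pd.DataFrame(cols, index=df.index)


def _transform_outcomes(df: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Transformed/standardized and dichotomized outcome columns.

    Moments (and the Box-Cox lambda) are computed once on the complete
    morphology columns and recorded in the manifest.
    """
    out = pd.DataFrame(index=df.index)
    meta = {}
    logv = st.log_transform(df["volume"].to_numpy())
    zv = st.z_standardize(logv.values)
    out["z_volume"] = zv.values
    meta["volume"] = {"transform": "log", "mean": zv.mean, "sd": zv.sd}
    bc = st.boxcox_transform(df["elongation"].to_numpy())
    ze = st.z_standardize(bc.values)
    out["z_elongation"] = ze.values
    meta["elongation"] = {
        "transform": "boxcox", "lambda": bc.lam, "mean": ze.mean, "sd": ze.sd
    }
    for name in ("sphericity", "flatness", "shape_index", "curvedness"):
        z = st.z_standardize(df[name].to_numpy())
        out[f"z_{name}"] = z.values
        meta[name] = {"transform": "identity", "mean": z.mean, "sd": z.sd}
    for name in ("shape_index", "curvedness"):
        out[f"hi_{name}"] = st.dichotomize_median(df[name].to_numpy())
        meta[name]["median"] = float(np.median(df[name]))
    return out, meta


# ---------------------------------------------------------------------------
# Main comparison
# ---------------------------------------------------------------------------

def run_sex_comparison(cohort: pd.DataFrame, config: AnalysisConfig) -> ResultsTable:
    """Transform -> impute -> fit per imputed set -> pool -> annotate."""
    df = prepare_analysis_table(cohort)
    if config.complete_case:
        df = df[df["smoking"].notna()].reset_index(drop=True)
    outcomes, transform_meta = _transform_outcomes(df)
    adjustment = tuple(
        t for t in config.adjustment if not (config.drop_smoking and t == "smoking_ever")
    )

    needs_smoking = "smoking_ever" in adjustment
    analysis = pd.concat([df, outcomes], axis=1)
    if needs_smoking and analysis["smoking"].isna().any():
        imp_cols = (
            ["smoking", "woman", "age", "hypertension", "size_mm", "location", "modality"]
            + list(outcomes.columns)
        )
        imputed = st.impute_chained(
            analysis[imp_cols],
            m=config.m,
            iterations=config.iterations,
            seed=config.seed,
        )
        tables = []
        for t in imputed:
            filled = analysis.copy()
            filled["smoking"] = t["smoking"]
            filled["smoking_ever"] = filled["smoking"].map(
                {"current": 1.0, "former": 1.0, "never": 0.0}
            )
            tables.append(filled)
        m_used = imputed.m
    else:
        tables = [analysis]
        m_used = 1

    rows = []
    model_specs = [(o, fam, tr, "primary") for o, (fam, tr) in PRIMARY_MODELS.items()]
    if config.exploratory_continuous:
        model_specs += [
            (o, fam, tr, "exploratory")
            for o, (fam, tr) in EXPLORATORY_MODELS.items()
        ]
    for outcome, family, transform, tier in model_specs:
        ycol = f"hi_{outcome}" if transform == "dichotomize" else f"z_{outcome}"
        for label, adjust in (("univariable", ()), ("multivariable", adjustment)):
            adj = adjust
            if outcome == "volume" and adj:
                adj = tuple(t for t in adj if t != "size_mm")
            fits = []
            for t in tables:
                design = build_design(t, adj)
                if family == "linear":
                    fits.append(st.fit_linear(t[ycol], design))
                else:
                    fits.append(st.fit_logistic(t[ycol], design))
            df_com = fits[0].df
            pooled = st.pool_rubin(fits, df_com=df_com)
            rows.append(_result_row(outcome, tier, family, label, pooled, len(df)))

    table = pd.DataFrame(rows)
    table = annotate_direction_frame(table)
    manifest = {
        "n_patients": int(len(df)),
        "n_complete_smoking": int(df["smoking"].notna().sum()),
        "m": m_used,
        "iterations": config.iterations,
        "seed": config.seed,
        "adjustment": list(adjustment),
        "drop_smoking": config.drop_smoking,
        "complete_case": config.complete_case,
        "transforms": transform_meta,
        "medians_by_sex": _medians_by_sex(df),
        "input_hash": _frame_hash(cohort),
    }
    return ResultsTable(table=table, manifest=manifest)


def _result_row(outcome, tier, family, analysis, est: st.EffectEstimate, n) -> dict:
    point, lo, hi = est.display_scale()
    return {
        "outcome": outcome,
        "tier": tier,
        "model": family,
        "analysis": analysis,
        "scale": "OR" if est.scale == "log_or" else "beta_sd",
        "estimate": point,
        "ci_low": lo,
        "ci_high": hi,
        "se": est.se,
        "df": est.df,
        "m": est.m,
        "n": n,
        "adjusted_for": ",".join(est.adjusted),
    }


def _medians_by_sex(df: pd.DataFrame) -> dict:
    out = {}
    scaled = {"sphericity", "elongation", "flatness", "shape_index", "curvedness"}
    for name in ("volume", "sphericity", "elongation", "flatness", "shape_index", "curvedness"):
        factor = 100.0 if name in scaled else 1.0
        per = {}
        for sex, sub in df.groupby("sex"):
            x = sub[name] * factor
            per[sex] = {
                "median": float(x.median()),
                "iqr": [float(x.quantile(0.25)), float(x.quantile(0.75))],
            }
        out[name] = per
    return out


def _frame_hash(df: pd.DataFrame) -> str:
    payload = pd.util.hash_pandas_object(df, index=False).to_numpy().tobytes()
    return hashlib.sha256(payload).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Direction annotation
# ---------------------------------------------------------------------------

def annotate_direction(outcome: str, estimate: float, ci_low: float, ci_high: float,
                       scale: str) -> str:
    """Label one estimate by the rupture-prone coding.

    A higher-in-women value of a parameter whose high values mark
    rupture-prone shape (and vice versa) yields "more rupture-prone in
    women"; estimates whose CI covers the null yield "no difference".
    """
    null = 1.0 if scale == "OR" else 0.0
    if ci_low <= null <= ci_high:
        return "no difference"
    woman_higher = estimate > null
    prone_high = RUPTURE_PRONE_HIGH[outcome]
    if woman_higher == prone_high:
        return "more rupture-prone in women"
    return "less rupture-prone in women"


def annotate_direction_frame(table: pd.DataFrame) -> pd.DataFrame:
    """Vector version of :func:`annotate_direction` over a results table."""
    out = table.copy()
    out["direction"] = [
        annotate_direction(r.outcome, r.estimate, r.ci_low, r.ci_high, r.scale)
        for r in out.itertuples()
    ]
    return out


# ---------------------------------------------------------------------------
# Sensitivity analyses
# ---------------------------------------------------------------------------

def run_sensitivity(cohort: pd.DataFrame, config: AnalysisConfig):
    """The two missing-data sensitivity analyses.

    1. smoking removed from the adjustment set (full cohort, no imputation
       needed);
    2. smoking kept, restricted to patients with observed smoking.
    """
    drop = replace_config(config, drop_smoking=True, complete_case=False)
    cc = replace_config(config, drop_smoking=False, complete_case=True)
    return run_sex_comparison(cohort, drop), run_sex_comparison(cohort, cc)


def replace_config(config: AnalysisConfig, **kwargs) -> AnalysisConfig:
    from dataclasses import replace

    return replace(config, **kwargs)


# ---------------------------------------------------------------------------
# Phantom-cohort integration mode
# ---------------------------------------------------------------------------

def simulate_phantom_cohort(
    n: int = 40, seed: int = 0, spacing: float = 0.4
) -> pd.DataFrame:
    """End-to-end small-n cohort: morphology measured from voxel phantoms.

    Covariates come from the tabular simulator; each patient's single
    aneurysm is a voxelized phantom (sphere, ellipsoid or bleb-decorated
    sphere, sex-linked size) quantified with the real morphometry path.
    Intended for integration tests; the tabular simulator covers large n.
    """
    from .cohort import MORPH_PARAMS, SimulationParams, generate_cohort
    from .phantoms import PhantomSpec, make_phantom

    params = SimulationParams(n=n, seed=seed, multiple_aneurysm_p=0.0)
    cohort = generate_cohort(params)
    rng = np.random.default_rng(seed + 1)
    rows = []
    for _, row in cohort.iterrows():
        radius = float(np.clip(row["size_mm"] / 2.0, 2.0, 6.0))
        kind = rng.choice(["sphere", "ellipsoid", "sphere_with_blebs"])
        if kind == "ellipsoid":
            ratios = rng.uniform(0.5, 0.95, size=2)
            spec = PhantomSpec(
                kind="ellipsoid",
                semi_axes_mm=(radius, radius * ratios[0], radius * ratios[0] * ratios[1]),
                seed=int(rng.integers(1 << 31)),
            )
        elif kind == "sphere_with_blebs":
            spec = PhantomSpec(
                kind="sphere_with_blebs",
                radius_mm=radius,
                n_blebs=int(rng.integers(1, 3)),
                bleb_radius_frac=float(rng.uniform(0.3, 0.6)),
                seed=int(rng.integers(1 << 31)),
            )
        else:
            spec = PhantomSpec(
                kind="sphere", radius_mm=radius,
                seed=int(rng.integers(1 << 31)),
            )
        # resolve the smallest feature with >= 5 voxels
        from dataclasses import replace as _replace

        h = min(spacing, spec.min_feature_mm / 5.0)
        spec = _replace(spec, spacing=(h,) * 3)
        cfg = MorphometryConfig(target_spacing=(h,) * 3, curvature_rings=3)
        mask, _ = make_phantom(spec)
        rec = analyze_mask(mask, cfg)
        rows.append(
            {
                "volume": rec.volume,
                "sphericity": rec.sphericity,
                "elongation": rec.elongation,
                "flatness": rec.flatness,
                "shape_index": rec.shape_index_median,
                "curvedness": rec.curvedness_median,
            }
        )
    measured = pd.DataFrame(rows, index=cohort.index)
    for p in MORPH_PARAMS:
        cohort[p] = measured[p]
    return cohort
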