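"""End-to-end orchestration: simulate -> metrics -> cognition -> stats.

``run_all`` drives the whole chain on a (by default simulated) cohort
and writes publication-style output tables:

* ``metrics.tsv`` — per subject-wave global network measures and
  connection-class strengths;
* ``composites.tsv`` — per subject-wave cognition composites;
* ``change_tests.tsv`` — two-wave change in every network measure and
  composite (mean difference, 95% CI, p);
* ``group_tests.tsv`` — WMH median-split group-by-time interactions and
  covariate-adjusted dementia group differences;
* ``regressions_svd.tsv`` — standardized betas of SVD markers on
  connection-class strengths (age/sex adjusted);
* ``regressions_cognition.tsv`` — standardized betas of network change
  on cognitive change (age/sex/education adjusted);
* ``mediation.tsv`` — WMH -> network measure -> dementia path models
  with bootstrap CIs;
* ``manifest.json`` — config hash, seed, attrition accounting, version.

Outputs are deterministic given (config, seed): identical runs produce
byte-identical tables.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .connectome import ConnectivityMatrix, write_edge_list, write_parcellation
from .network_metrics import (
    EDGE_CLASSES,
    classify_edges,
    compute_global_metrics,
)
from .stats import (
    adjusted_group_difference,
    fit_mediation,
    group_time_interaction,
    log_transform_wmh,
    median_split,
    paired_change_test,
    standardized_regression,
)
from .synthetic_cohort import (
    COMPOSITES,
    GeneratorConfig,
    SyntheticCohort,
    config_from_jsonable,
    generate_cohort,
)

__all__ = ["run_all", "metrics_table", "significance_stars"]

NETWORK_MEASURES = (
    "density", "total_strength", "global_efficiency",
    "rich_club_strength", "feeder_strength", "peripheral_strength",
)

_FLOAT_FMT = "%.10g"


def significance_stars(p: float) -> str:
    """Stars matching the table legends: * <0.05, ** <0.01, *** <0.001."""
    if not np.isfinite(p):
        return ""
    return "***" if p < 0.001 else "**" if p < 0.01 else "*" if p < 0.05 else ""


def metrics_table(
    matrices: dict[tuple[str, str], ConnectivityMatrix]
) -> pd.DataFrame:
    """One row per subject-wave: global measures + class decomposition."""
    rows = []
    for (subject_id, wave), mat in matrices.items():
        gm = compute_global_metrics(mat)
        part = classify_edges(mat)
        row = {
            "subject_id": subject_id,
            "wave": wave,
            "density": gm.density,
            "total_strength": gm.total_strength,
            "global_efficiency": gm.global_efficiency,
        }
        for cls in EDGE_CLASSES:
            key = "rich_club" if cls == "rich_club" else cls
            row[f"{key}_strength"] = part.class_strengths[cls]
            row[f"{key}_count"] = part.class_counts[cls]
        rows.append(row)
    return pd.DataFrame(rows).sort_values(["subject_id", "wave"]).reset_index(drop=True)


def _wide_by_wave(df: pd.DataFrame, value_cols: list[str]) -> pd.DataFrame:
    """Pivot a long subject-wave table to baseline/followup columns."""
    wide = df.pivot(index="subject_id", columns="wave", values=value_cols)
    wide.columns = [f"{col}_{wave}" for col, wave in wide.columns]
    return wide.reset_index()


def _change_tests(wide: pd.DataFrame, measures) -> pd.DataFrame:
    rows = []
    for m in measures:
        res = paired_change_test(wide[f"{m}_baseline"], wide[f"{m}_followup"])
        rows.append({
            "measure": m,
            "mean_difference": res.mean_difference,
            "ci_low": res.ci95[0],
            "ci_high": res.ci95[1],
            "p": res.p_value,
            "stars": significance_stars(res.p_value),
            "n": res.n,
        })
    return pd.DataFrame(rows)


def run_all(
    config: dict | None = None,
    out_dir: str | Path = "svdnet_run",
    seed: int | None = None,
    cohort: SyntheticCohort | None = None,
) -> Path:
    """Run the full pipeline and write all output tables.

    ``config`` keys: ``seed`` (int), ``generator`` (GeneratorConfig field
    overrides), ``mediation`` ({"n_boot": int}), ``write_matrices``
    (bool, default False).  A pre-built ``cohort`` skips simulation.
    Returns the output directory.  The manifest is written even when a
    stage fails.
    """
    config = dict(config or {})
    if seed is None:
        seed = int(config.get("seed", 0))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": seed,
        "config_hash": hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "config": config,
        "started_utc": time.strftime("%Y-%m-%dT%H:%M:%SZ", time.gmtime()),
        "stages": {},
        "exclusions": [],
    }
    try:
        _run_stages(config, out, seed, cohort, manifest)
        manifest["status"] = "ok"
    except Exception as exc:
        manifest["status"] = f"failed: {type(exc).__name__}: {exc}"
        raise
    finally:
        manifest["finished_utc"] = time.strftime("%Y-%m-%dT%H:%M:%SZ", time.gmtime())
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return out


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def _run_stages(config, out, seed, cohort, manifest):
    # --- stage: cohort -----------------------------------------------
    if cohort is None:
        gen_cfg = GeneratorConfig(**config.get("generator", {}))
        cohort = generate_cohort(gen_cfg, seed=seed)
    df = cohort.cohort
    n_in = df["subject_id"].nunique()
    manifest["stages"]["cohort"] = {"subjects_in": n_in}

    # exclusion: subjects missing either wave
    wave_counts = df.groupby("subject_id")["wave"].nunique()
    incomplete = wave_counts[wave_counts < 2].index
    for sid in incomplete:
        manifest["exclusions"].append({"subject_id": sid, "reason": "missing_wave"})
    df = df[~df["subject_id"].isin(incomplete)]
    n_kept = df["subject_id"].nunique()
    manifest["stages"]["cohort"]["subjects_kept"] = n_kept
    manifest["stages"]["cohort"]["subjects_excluded"] = n_in - n_kept

    _write(df.sort_values(["subject_id", "wave"]), out / "cohort.tsv")
    if config.get("write_matrices", False):
        mdir = out / "matrices"
        mdir.mkdir(exist_ok=True)
        write_parcellation(cohort.config.parcellation, out / "parcellation.csv")
        for (sid, wave), mat in cohort.matrices.items():
            write_edge_list(mat, mdir / f"{sid}_{wave}.tsv")

    # --- stage: network metrics --------------------------------------
    keep = set(df["subject_id"])
    mats = {k: v for k, v in cohort.matrices.items() if k[0] in keep}
    met = metrics_table(mats)
    _write(met, out / "metrics.tsv")
    manifest["stages"]["metrics"] = {"rows": len(met)}

    # --- stage: cognition composites ---------------------------------
    comp = df[["subject_id", "wave", *COMPOSITES]].sort_values(
        ["subject_id", "wave"]
    ).reset_index(drop=True)
    _write(comp, out / "composites.tsv")
    manifest["stages"]["cognition"] = {"rows": len(comp)}

    # --- stage: longitudinal change ----------------------------------
    met_wide = _wide_by_wave(met, list(NETWORK_MEASURES))
    comp_wide = _wide_by_wave(comp, list(COMPOSITES))
    base = df[df["wave"] == "baseline"].set_index("subject_id")
    merged = met_wide.merge(comp_wide, on="subject_id").merge(
        base[["age", "male", "education_years", "wmh_ml", "lacune_count",
              "microbleed_count", "dementia_followup"]],
        left_on="subject_id", right_index=True,
    )
    fu = df[df["wave"] == "followup"].set_index("subject_id")
    merged["wmh_progression_ml"] = (
        fu.loc[merged["subject_id"], "wmh_ml"].to_numpy()
        - merged["wmh_ml"].to_numpy()
    )
    change = _change_tests(merged, list(NETWORK_MEASURES) + list(COMPOSITES))
    _write(change, out / "change_tests.tsv")
    manifest["stages"]["change_tests"] = {"rows": len(change)}

    # --- stage: group tests ------------------------------------------
    wmh_group = median_split(merged["wmh_ml"].to_numpy())
    rows = []
    for m in NETWORK_MEASURES:
        p_int = group_time_interaction(
            merged[f"{m}_baseline"].to_numpy(),
            merged[f"{m}_followup"].to_numpy(),
            wmh_group,
        )
        rows.append({"test": f"wmh_group_x_time[{m}]", "estimate": np.nan,
                     "ci_low": np.nan, "ci_high": np.nan, "p": p_int,
                     "stars": significance_stars(p_int), "n": len(merged)})
    covs = merged[["age", "male", "education_years"]]
    for m in NETWORK_MEASURES:
        res = adjusted_group_difference(
            merged[f"{m}_baseline"].to_numpy(),
            np.where(merged["dementia_followup"] == 1, "dementia", "no_dementia"),
            covariates=covs,
        )
        rows.append({"test": f"dementia_baseline_difference[{m}]",
                     "estimate": res.mean_difference,
                     "ci_low": res.ci95[0], "ci_high": res.ci95[1],
                     "p": res.p_value, "stars": significance_stars(res.p_value),
                     "n": res.n})
    _write(pd.DataFrame(rows), out / "group_tests.tsv")
    manifest["stages"]["group_tests"] = {"rows": len(rows)}

    # --- stage: SVD-marker regressions -------------------------------
    merged["log_wmh"] = log_transform_wmh(merged["wmh_ml"].to_numpy())
    svd_predictors = ["log_wmh", "lacune_count", "microbleed_count"]
    rows = []
    for outcome in ("rich_club_strength", "feeder_strength", "peripheral_strength"):
        for pred in svd_predictors:
            res = standardized_regression(
                merged[f"{outcome}_baseline"].to_numpy(),
                merged[[pred]],
                covariates=merged[["age", "male"]],
                categorical_covariates=("male",),
                outcome_name=outcome,
            )
            t = res.table.loc[pred]
            rows.append({"outcome": outcome, "predictor": pred,
                         "beta": t["beta"], "ci_low": t["ci_low"],
                         "ci_high": t["ci_high"], "p": t["p"],
                         "stars": significance_stars(t["p"]), "n": res.n})
    _write(pd.DataFrame(rows), out / "regressions_svd.tsv")
    manifest["stages"]["regressions_svd"] = {"rows": len(rows)}

    # --- stage: cognition regressions --------------------------------
    rows = []
    for comp_name in COMPOSITES:
        d_y = merged[f"{comp_name}_followup"] - merged[f"{comp_name}_baseline"]
        for m in NETWORK_MEASURES:
            d_x = merged[f"{m}_followup"] - merged[f"{m}_baseline"]
            res = standardized_regression(
                d_y.to_numpy(),
                pd.DataFrame({f"delta_{m}": d_x}),
                covariates=merged[["age", "male", "education_years"]],
                categorical_covariates=("male",),
                outcome_name=f"delta_{comp_name}",
            )
            t = res.table.loc[f"delta_{m}"]
            rows.append({"outcome": f"delta_{comp_name}", "predictor": f"delta_{m}",
                         "beta": t["beta"], "ci_low": t["ci_low"],
                         "ci_high": t["ci_high"], "p": t["p"],
                         "stars": significance_stars(t["p"]), "n": res.n})
    _write(pd.DataFrame(rows), out / "regressions_cognition.tsv")
    manifest["stages"]["regressions_cognition"] = {"rows": len(rows)}

    # --- stage: mediation --------------------------------------------
    n_boot = int(config.get("mediation", {}).get("n_boot", 2000))
    rows = []
    for k, m in enumerate(
        ("global_efficiency", "rich_club_strength", "feeder_strength",
         "peripheral_strength")
    ):
        res = fit_mediation(
            merged["log_wmh"].to_numpy(),
            merged[f"{m}_baseline"].to_numpy(),
            merged["dementia_followup"].to_numpy(),
            covariates=merged[["age", "male", "education_years"]],
            y_binary=True,
            n_boot=n_boot,
            seed=(seed * 1000 + k) % (2**31),
        )
        rows.append({
            "mediator": m, "a": res.a, "a_p": res.a_p, "b": res.b, "b_p": res.b_p,
            "c_prime": res.c_prime, "c_prime_p": res.c_prime_p,
            "indirect": res.indirect,
            "indirect_ci_low": res.indirect_ci95[0],
            "indirect_ci_high": res.indirect_ci95[1],
            "indirect_p": res.indirect_boot_p,
            "direct_ci_low": res.direct_ci95[0],
            "direct_ci_high": res.direct_ci95[1],
            "direct_p": res.direct_boot_p,
            "n": res.n, "n_boot": res.n_boot,
        })
    _write(pd.DataFrame(rows), out / "mediation.tsv")
    manifest["stages"]["mediation"] = {"rows": len(rows)}
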