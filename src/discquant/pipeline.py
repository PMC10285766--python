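"""End-to-end pipeline: cohort -> per-specimen measures -> tables and statistics.

The report bundle mirrors the study's result structure: a normalized
removed-volume table per technique, regional localization grids, intact
vs post-nuclectomy stiffness with percent reductions, disc-height changes,
mass estimates, and a statistics block (assumption checks, paired tests,
one-way ANOVA + Tukey, correlations) with raw p-values throughout.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import geometry, mass, mechanics, stats, volumetry
from .config import RunConfig
from .containers import LabelVolume, SpecimenRecord
from .io import read_label_volume, read_series
from .synthetic import CohortParams, gen_cohort

#: Measures compared between techniques in the report.
GROUP_MEASURES = (
    "normalized_removal_pct",
    "removed_mm3",
    "toe_reduction_pct",
    "linear_reduction_pct",
    "height_drop_mm",
    "height_drop_pct",
    "wet_mass_g",
    "dry_mass_g",
)


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; the stage name prefixes the message."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[stage: {stage}] {cause}")
        self.stage = stage
        self.cause = cause


def _run_stage(stage: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise PipelineStageError(stage, exc) from exc


def process_specimen(
    record: SpecimenRecord, asset: dict, config: RunConfig
) -> dict:
    """Compute every per-specimen measure from its volumes and series."""
    out: dict = {"specimen_id": record.specimen_id, "technique": record.technique}

    post_vol: LabelVolume = asset["post_volume"]
    pre_vol: LabelVolume | None = asset.get("pre_volume")

    vol = _run_stage("volumetry", volumetry.removed_volume, post_vol)
    out["removed_mm3"] = vol.removed_mm3
    out["disc_mm3"] = vol.disc_mm3
    out["normalized_removal_pct"] = vol.normalized_removal_pct

    table, summary, _ = _run_stage(
        "localization",
        geometry.localize_volume,
        post_vol,
        config.partition_fractions,
        config.radius_mode,
        record.entry_side,
    )
    out["localization"] = table
    out["pct_within_0.4W"] = summary["pct_within_0.4W"]
    out["lateral_width_mm"] = summary["lateral_width_mm"]

    if pre_vol is not None:
        h_pre = _run_stage("disc_height", volumetry.disc_height, pre_vol)
        h_post = _run_stage("disc_height", volumetry.disc_height, post_vol)
        out["height_pre_mm"] = h_pre.height_mm
        out["height_post_mm"] = h_post.height_mm
        out["height_drop_mm"] = h_pre.height_mm - h_post.height_mm
        out["height_drop_pct"] = 100.0 * out["height_drop_mm"] / h_pre.height_mm

    if "load_pre" in asset and "load_post" in asset:
        s_pre = _run_stage(
            "mechanics",
            mechanics.extract_stiffness,
            asset["load_pre"],
            config.toe_window,
            config.linear_window,
        )
        s_post = _run_stage(
            "mechanics",
            mechanics.extract_stiffness,
            asset["load_post"],
            config.toe_window,
            config.linear_window,
        )
        pc = mechanics.precondition_check(
            s_pre.per_cycle_k_toe, config.precondition_threshold_pct
        )
        change = mechanics.stiffness_change(s_pre, s_post)
        out.update(
            k_toe_pre=s_pre.k_toe,
            k_lin_pre=s_pre.k_lin,
            k_toe_post=s_post.k_toe,
            k_lin_post=s_post.k_lin,
            precondition_passed=pc["passed"],
            precondition_final_delta_pct=pc["final_delta_pct"],
            toe_reduction_pct=change["toe_reduction_pct"],
            linear_reduction_pct=change["linear_reduction_pct"],
        )

    if "mass_series" in asset:
        est = _run_stage("mass", mass.estimate_ablated_mass, asset["mass_series"])
        out["wet_mass_g"] = est.estimate_g
        out["mass_fit_r2_pre"] = est.pre.r2
        out["mass_fit_r2_post"] = est.post.r2
    elif np.isfinite(record.wet_mass_removed_g):
        out["wet_mass_g"] = record.wet_mass_removed_g

    if np.isfinite(record.dry_mass_removed_g):
        out["dry_mass_g"] = record.dry_mass_removed_g
    elif "wet_mass_g" in out:
        # thermal removal: dry mass inferred via the tissue water fraction
        out["dry_mass_g"] = mass.dry_mass(out["wet_mass_g"], config.water_fraction)
    if "wet_mass_g" in out:
        out["brinckman_height_loss_mm"] = mass.brinckman_height_loss(
            out["wet_mass_g"], config.brinckman_mm_per_g
        )
    return out


def build_group_table(results: list[dict]) -> pd.DataFrame:
    """Long-format (specimen, technique, measure, value) table for statistics."""
    rows = []
    for r in results:
        for measure in GROUP_MEASURES:
            if measure in r and np.isfinite(r[measure]):
                rows.append(
                    {
                        "specimen_id": r["specimen_id"],
                        "technique": r["technique"],
                        "measure": measure,
                        "value": float(r[measure]),
                    }
                )
    df = pd.DataFrame(rows)
    if len(df) and df.duplicated(["specimen_id", "measure"]).any():
        raise ValueError("duplicate (specimen, measure) rows in group table")
    return df


def compute_statistics(results: list[dict], group_table: pd.DataFrame) -> dict:
    """Assumption checks, between-technique ANOVA/Tukey and paired tests."""
    out: dict = {"group_comparisons": {}, "paired_tests": {}, "assumptions": {}}
    techniques = sorted({r["technique"] for r in results})
    if len(techniques) < 2:
        out["notice"] = "single-technique cohort: group comparisons skipped"
        return out

    for measure in GROUP_MEASURES:
        sub = group_table[group_table["measure"] == measure]
        groups = {
            t: sub[sub["technique"] == t]["value"].to_numpy()
            for t in techniques
            if (sub["technique"] == t).sum() >= 2
        }
        if len(groups) < 2:
            continue
        out["group_comparisons"][measure] = stats.group_comparison(groups)
        if all(v.size >= 3 for v in groups.values()):
            out["assumptions"][measure] = stats.check_assumptions(groups)

    # paired intact-vs-post stiffness tests per technique
    df = pd.DataFrame(results)
    for region, pre_c, post_c in (
        ("toe", "k_toe_pre", "k_toe_post"),
        ("linear", "k_lin_pre", "k_lin_post"),
    ):
        if pre_c not in df.columns:
            continue
        for t in techniques:
            sub = df[(df["technique"] == t)].dropna(subset=[pre_c, post_c])
            if len(sub) >= 2:
                out["paired_tests"][f"{region}_stiffness_{t}"] = stats.paired_change_test(
                    sub[pre_c].to_numpy(), sub[post_c].to_numpy()
                )

    # association between dry mass removed and cavity volume, per technique
    out["correlations"] = {}
    if "dry_mass_g" in df.columns and "removed_mm3" in df.columns:
        for t in techniques:
            sub = df[df["technique"] == t].dropna(subset=["dry_mass_g", "removed_mm3"])
            if len(sub) >= 3 and sub["dry_mass_g"].nunique() > 1:
                out["correlations"][f"dry_mass_vs_cavity_volume_{t}"] = stats.correlate(
                    sub["dry_mass_g"].to_numpy(), sub["removed_mm3"].to_numpy()
                )
    return out


def build_report(
    results: list[dict], config: RunConfig, seed: int
) -> dict:
    """Assemble the report bundle: one table per figure analogue plus stats."""
    if not results:
        raise ValueError("no specimen results to report")
    df = pd.DataFrame([{k: v for k, v in r.items() if k != "localization"} for r in results])
    required = ["removed_mm3", "disc_mm3", "normalized_removal_pct"]
    gaps = [
        (r["specimen_id"], c)
        for r in results
        for c in required
        if c not in r or not np.isfinite(r[c])
    ]
    if gaps:
        raise ValueError(f"missing measures for specimens: {gaps}")

    volumes = df[
        ["specimen_id", "technique", "removed_mm3", "disc_mm3", "normalized_removal_pct"]
    ].copy()

    loc_rows = []
    for r in results:
        t = r["localization"].copy()
        t.insert(0, "specimen_id", r["specimen_id"])
        t.insert(1, "technique", r["technique"])
        loc_rows.append(t)
    localization = pd.concat(loc_rows, ignore_index=True)
    localization_group = (
        localization.groupby(["technique", "quadrant", "band"], as_index=False)[
            ["pct_of_removed", "pct_of_region_intact"]
        ].mean()
    )

    stiff_cols = [
        c
        for c in (
            "k_toe_pre",
            "k_toe_post",
            "k_lin_pre",
            "k_lin_post",
            "toe_reduction_pct",
            "linear_reduction_pct",
            "precondition_passed",
            "precondition_final_delta_pct",
        )
        if c in df.columns
    ]
    stiffness = df[["specimen_id", "technique", *stiff_cols]].copy()

    height_cols = [
        c
        for c in ("height_pre_mm", "height_post_mm", "height_drop_mm", "height_drop_pct")
        if c in df.columns
    ]
    heights = df[["specimen_id", "technique", *height_cols]].copy()

    mass_cols = [
        c
        for c in ("wet_mass_g", "dry_mass_g", "brinckman_height_loss_mm", "mass_fit_r2_pre", "mass_fit_r2_post")
        if c in df.columns
    ]
    masses = df[["specimen_id", "technique", *mass_cols]].copy()

    group_table = build_group_table(results)
    statistics = compute_statistics(results, group_table)
    group_summary = (
        group_table.groupby(["technique", "measure"])["value"]
        .agg(["mean", "std", "count"])
        .reset_index()
    )

    return {
        "tables": {
            "volumes": volumes,
            "localization": localization,
            "localization_group": localization_group,
            "stiffness": stiffness,
            "heights": heights,
            "masses": masses,
            "group_table": group_table,
            "group_summary": group_summary,
        },
        "stats": statistics,
        "config": config.to_dict(),
        "seed": int(seed),
        "n_specimens": int(len(results)),
    }


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, float)):
        return float(obj)
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    return obj


def write_report(report: dict, out_dir: str | Path) -> Path:
    """Write the report bundle: CSV per table plus a JSON stats/config file."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, table in report["tables"].items():
        table.to_csv(out / f"{name}.csv", index=False)
    payload = {k: _jsonable(v) for k, v in report.items() if k != "tables"}
    with open(out / "report.json", "w") as fh:
        json.dump(payload, fh, sort_keys=True, indent=1)
    return out / "report.json"


def _load_manifest_assets(entry: dict) -> dict:
    asset: dict = {}
    asset["post_volume"] = read_label_volume(entry["post_volume"])
    if "pre_volume" in entry:
        asset["pre_volume"] = read_label_volume(entry["pre_volume"])
    if "load_pre" in entry:
        asset["load_pre"] = read_series(entry["load_pre"], "load")
    if "load_post" in entry:
        asset["load_post"] = read_series(entry["load_post"], "load")
    if "mass_series" in entry:
        asset["mass_series"] = read_series(entry["mass_series"], "mass")
    return asset


def run_pipeline(
    config: RunConfig | None = None,
    manifest: list[dict] | None = None,
    cohort_params: CohortParams | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """Run the full analysis and return (optionally write) the report bundle.

    With no manifest a synthetic cohort is generated from ``cohort_params``
    (default: fifteen specimens, five per technique) under the config seed;
    a manifest is a list of per-specimen dicts with a ``record``
    (SpecimenRecord or its field dict) and file paths ``post_volume`` and
    optionally ``pre_volume``, ``load_pre``, ``load_post``, ``mass_series``.
    """
    config = config or RunConfig()
    if manifest is not None and len(manifest) == 0:
        raise PipelineStageError("manifest", ValueError("empty input manifest"))

    if manifest is None:
        records, truth, assets = _run_stage(
            "synthesis",
            gen_cohort,
            cohort_params,
            config.seed,
            True,
            True,
        )
        pairs = [(rec, assets[rec.specimen_id]) for rec in records]
    else:
        pairs = []
        truth = None
        for entry in manifest:
            rec = entry["record"]
            if isinstance(rec, dict):
                rec = SpecimenRecord(**rec)
            pairs.append((rec, _run_stage("io", _load_manifest_assets, entry)))

    results = [process_specimen(rec, asset, config) for rec, asset in pairs]
    report = _run_stage("report", build_report, results, config, config.seed)
    if truth is not None:
        report["tables"]["truth"] = truth
    if out_dir is not None:
        _run_stage("write", write_report, report, out_dir)
    return report
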