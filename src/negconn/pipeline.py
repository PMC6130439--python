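"""End-to-end orchestration: simulate -> motion QC -> connectivity -> mask
-> metric -> CPT scoring -> inference -> report.

The pipeline is deterministic under a single global seed, fanned out into
named substreams per stage so any stage re-run in isolation reproduces its
output. The report collects per-scan accounting (eligibility, minutes of
clean data, mean FD, exclusion reason), the mask summary, every model
table, and the configuration that produced them.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .behavior import counts_from_trials, score_cpt
from .cohort import Cohort, SyntheticConfig, generate_cohort, toy_parcellation
from .connectivity import correlation_matrix
from .mask import MaskRule, average_negative_connectivity, build_mask, region_importance
from .motion import (
    InsufficientCleanDataError,
    censor_frames,
    compute_fd,
    secondary_fd_qc,
    select_clean_frames,
)
from .stats import (
    ModelSpec,
    brain_behavior_fit,
    edgewise_fit,
    fit_lmm,
    gender_balanced_permutation,
    select_model,
    summed_t_map,
)
from .mask import edge_values

logger = logging.getLogger(__name__)

STAGES = ("simulate", "motion", "connectivity", "mask", "metric", "behavior", "inference")


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


def default_config() -> dict:
    """Demo configuration: small enough to run end-to-end in minutes."""
    return {
        "seed": 0,
        "cohort": {
            "n_subjects_per_group": 40,
            "n_frames": 200,
            "tr_seconds": 2.0,
        },
        "reference": {"n_scans": 20},
        "motion": {"fd_threshold_mm": 0.2, "target_minutes": 4.0, "head_radius_mm": 50.0},
        "mask": {"scope": "dmn_to_taskpos", "rule": "threshold:-0.15"},
        "qc": {"alpha": 0.05},
        "inference": {"n_perm": 100},
    }


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    base = default_config()
    for key, val in (cfg or {}).items():
        if isinstance(val, dict) and key in base:
            base[key].update(val)
        else:
            base[key] = val
    return base


def _stage_seed(seed: int, stage: str) -> int:
    """Named substream: stable per-stage seed below 2**31."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def run_pipeline(config: dict | str | Path, out_dir: str | Path | None = None) -> dict:
    """Execute the full analysis and return the machine-readable report."""
    if not isinstance(config, dict):
        config = load_config(config)
    seed = int(config.get("seed", 0))
    report: dict = {"version": __version__, "seed": seed, "stages": {}}
    report["config_hash"] = hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()

    # --- simulate ------------------------------------------------------
    try:
        syn_kwargs = dict(config.get("cohort", {}))
        syn = SyntheticConfig(seed=_stage_seed(seed, "cohort"), **syn_kwargs)
        cohort = generate_cohort(syn, emit_timeseries=True)
        ref_cfg = config.get("reference", {})
        n_ref = int(ref_cfg.get("n_scans", 20))
        ref_syn = SyntheticConfig(
            seed=_stage_seed(seed, "reference"),
            n_subjects_per_group=max(n_ref // 2, 1),
            p_wave2=0.0,
            delta_group=0.0,
            delta_sex=0.0,
            beta_age=0.0,
            n_frames=syn.n_frames,
            tr_seconds=syn.tr_seconds,
            parcellation=syn.parcellation,
        )
        reference = generate_cohort(ref_syn, emit_timeseries=True)
    except Exception as exc:
        raise StageError("simulate", str(exc)) from exc
    report["stages"]["simulate"] = {
        "n_scans": len(cohort.records),
        "n_subjects": cohort.records["subject_id"].nunique(),
        "n_reference_scans": len(reference.records),
    }

    # --- motion QC -----------------------------------------------------
    mo = config.get("motion", {})
    threshold = float(mo.get("fd_threshold_mm", 0.2))
    minutes = float(mo.get("target_minutes", 4.0))
    radius = float(mo.get("head_radius_mm", 50.0))
    rng_select = np.random.default_rng(_stage_seed(seed, "frame_selection"))

    def motion_pass(coh: Cohort, stage: str) -> tuple[dict, list[dict]]:
        masks: dict[str, object] = {}
        accounting = []
        for scan_id, ts in coh.timeseries.items():
            trace = coh.motion.get(scan_id)
            if trace is None:
                raise StageError(stage, f"missing motion trace for scan {scan_id}")
            if trace.n_frames != ts.n_frames:
                raise StageError(stage, f"frame count mismatch for scan {scan_id}")
            fd = compute_fd(trace, head_radius_mm=radius)
            censored = censor_frames(fd, ts.tr_seconds, threshold_mm=threshold)
            entry = {
                "scan_id": scan_id,
                "minutes_clean": censored.minutes_kept,
                "mean_fd": fd.mean_over(censored.keep),
                "eligible": None,
                "reason": "",
            }
            try:
                masks[scan_id] = select_clean_frames(censored, minutes, rng_select)
                entry["eligible"] = True
            except InsufficientCleanDataError as exc:
                entry["eligible"] = False
                entry["reason"] = str(exc)
            accounting.append(entry)
        return masks, accounting

    masks, accounting = motion_pass(cohort, "motion")
    ref_masks, _ = motion_pass(reference, "motion")
    acct = pd.DataFrame(accounting)
    report["stages"]["motion"] = {
        "fd_threshold_mm": threshold,
        "target_minutes": minutes,
        "n_eligible": int(acct["eligible"].sum()),
        "n_excluded_motion": int((~acct["eligible"]).sum()),
    }

    # --- connectivity --------------------------------------------------
    mats = {
        sid: correlation_matrix(cohort.timeseries[sid], m) for sid, m in masks.items()
    }
    ref_mats = [
        correlation_matrix(reference.timeseries[sid], m) for sid, m in ref_masks.items()
    ]
    report["stages"]["connectivity"] = {"n_matrices": len(mats)}

    # --- mask ----------------------------------------------------------
    mk = config.get("mask", {})
    rule = MaskRule.parse(str(mk.get("rule", "threshold:-0.15")))
    scope = str(mk.get("scope", "dmn_to_taskpos"))
    parc = syn.parcellation
    try:
        mask = build_mask(ref_mats, parc, scope=scope, rule=rule)
    except Exception as exc:
        raise StageError("mask", str(exc)) from exc
    importance = region_importance(mask, parc.n_rois)
    report["stages"]["mask"] = {
        "scope": scope,
        "rule": f"{rule.kind}:{rule.value}",
        "n_candidates": mask.n_candidates,
        "n_edges": mask.n_edges,
        "density_percent": mask.density_percent,
        "region_importance": importance.tolist(),
    }

    # --- metric + behavior --------------------------------------------
    fd_by_scan = acct.set_index("scan_id")
    records = cohort.records[cohort.records["scan_id"].isin(mats)].copy()
    records["mean_fd"] = records["scan_id"].map(fd_by_scan["mean_fd"])
    records["avg_neg_conn"] = [
        average_negative_connectivity(mats[sid], mask) for sid in records["scan_id"]
    ]
    d_easy, d_diff = [], []
    for sid in records["scan_id"]:
        res = score_cpt(counts_from_trials(cohort.trials[sid]))
        d_easy.append(res.dprime_easy)
        d_diff.append(res.dprime_difficult)
    records["dprime_easy"] = d_easy
    records["dprime_difficult"] = d_diff
    report["stages"]["metric"] = {
        "mean_avg_neg_conn": float(records["avg_neg_conn"].mean()),
        "by_group": records.groupby("group")["avg_neg_conn"].mean().to_dict(),
    }
    report["stages"]["behavior"] = {
        "dprime_easy_by_group": records.groupby("group")["dprime_easy"].mean().to_dict(),
        "dprime_difficult_by_group": records.groupby("group")["dprime_difficult"].mean().to_dict(),
    }

    # --- secondary FD QC ----------------------------------------------
    qc = config.get("qc", {})
    removed_idx = secondary_fd_qc(records, alpha=float(qc.get("alpha", 0.05)))
    removed_scans = records.iloc[removed_idx]["scan_id"].tolist()
    records = records.drop(records.index[removed_idx]).reset_index(drop=True)
    report["stages"]["motion"]["n_excluded_secondary_qc"] = len(removed_scans)
    report["stages"]["motion"]["secondary_qc_removed"] = removed_scans

    total = len(cohort.records)
    n_in = len(records)
    n_motion_out = int((~acct["eligible"]).sum())
    assert n_in + n_motion_out + len(removed_scans) == total

    # --- inference -----------------------------------------------------
    inf = config.get("inference", {})
    fits = [fit_lmm(records, "avg_neg_conn", spec)
            for spec in (ModelSpec.model1(), ModelSpec.model2(), ModelSpec.model3())]
    best, aic_table = select_model(fits)

    edge_z = np.array([edge_values(mats[sid], mask) for sid in records["scan_id"]])
    estats = edgewise_fit(edge_z, records, mask)
    tmap = summed_t_map(estats, "adhd", "positive", parc.n_rois)

    n_perm = int(inf.get("n_perm", 100))
    perm_mean_p, _ = gender_balanced_permutation(
        records, n_perm=n_perm, seed=_stage_seed(seed, "permutation")
    )
    behav = brain_behavior_fit(records, which_dprime="both")

    report["stages"]["inference"] = {
        "models": {
            f.spec.name: {
                "aic": f.aic,
                "df": f.df_model,
                "terms": f.terms.reset_index().to_dict(orient="records"),
            }
            for f in fits
        },
        "best_model": best.spec.name,
        "aic_table": aic_table.to_dict(orient="records"),
        "edgewise_n_discoveries_group": int(
            (estats.for_term("adhd")["qvalue"] < 0.05).sum()
        ),
        "summed_t_group_positive": tmap.tolist(),
        "permutation": {"n_perm": n_perm, "mean_p": perm_mean_p.to_dict()},
        "brain_behavior": behav.terms.reset_index().to_dict(orient="records"),
    }
    report["accounting"] = acct.to_dict(orient="records")
    report["n_scans_analyzed"] = n_in

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=float)
        records.to_csv(out / "records.csv", index=False)
        mask.save(out / "mask.tsv")
        with open(out / "summary.txt", "w") as fh:
            fh.write(summarize(report))
    return report


def summarize(report: dict) -> str:
    """Plain-text digest of a pipeline report."""
    s = report["stages"]
    best = s["inference"]["best_model"]
    terms = {
        row["term"]: row
        for row in s["inference"]["models"][best]["terms"]
    }
    lines = [
        f"negconn {report['version']} pipeline report (seed {report['seed']})",
        f"scans simulated: {s['simulate']['n_scans']}; "
        f"motion-eligible: {s['motion']['n_eligible']}; "
        f"secondary QC removed: {s['motion'].get('n_excluded_secondary_qc', 0)}; "
        f"analyzed: {report['n_scans_analyzed']}",
        f"mask: {s['mask']['n_edges']}/{s['mask']['n_candidates']} edges "
        f"({s['mask']['density_percent']:.2f}% density, {s['mask']['rule']})",
        f"mean metric by group: "
        + ", ".join(f"{g}={v:.3f}" for g, v in s["metric"]["by_group"].items()),
        f"best model by AIC: {best}",
    ]
    for name in ("adhd", "female", "age_c"):
        if name in terms:
            row = terms[name]
            lines.append(
                f"  {name}: B={row['estimate']:+.4f}, t={row['tvalue']:+.2f}, "
                f"p={row['pvalue']:.4f}"
            )
    bb = {row["term"]: row for row in s["inference"]["brain_behavior"]}
    if "avg_neg_conn" in bb:
        row = bb["avg_neg_conn"]
        lines.append(
            f"  d' ~ connectivity: B={row['estimate']:+.3f}, p={row['pvalue']:.4f}"
        )
    return "\n".join(lines) + "\n"
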