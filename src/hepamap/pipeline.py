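"""End-to-end study pipeline.

Drives every stage over a simulated (or loaded) two-cohort study: IVIM map
fitting and whole-liver summaries for all subjects; T1 / dT1% and HEF maps
for patients; Dice registration QC; group comparison (Mann-Whitney) and ROC
with bootstrap validation of the IVIM parameters; and voxelwise Pearson
correlation of the patient-group maps on a single ROI slice with Fisher-Z
pooling.  Reports are plain dicts of records (JSON-serializable) with a
provenance block and a deterministic digest.
"""

from __future__ import annotations

import hashlib
import json

import numpy as np
import pandas as pd

from . import __version__
from .hef import hef_map
from .io import PipelineConfig, config_hash
from .ivim import (McmcConfig, fit_ivim_bayes, fit_ivim_lsq,
                   global_liver_summary, median_filter_slicewise)
from .stats import (dice_similarity, fisher_z_average, mann_whitney_u,
                    roc_analysis, bootstrap_validate, voxelwise_pearson)
from .t1 import SPGRAcquisition, delta_t1_percent, fit_t1_dfa

__all__ = ["run_pipeline", "subject_ivim_summary", "report_digest"]

IVIM_PARAMS = ("d_slow", "f_p", "d_fast")
_CORR_PAIRS = [
    ("hef", "d_slow"), ("hef", "d_fast"), ("hef", "f_p"),
    ("hef", "t1_post"), ("hef", "delta_t1"),
    ("d_slow", "t1_post"), ("d_slow", "delta_t1"),
    ("d_fast", "f_p"), ("d_fast", "t1_post"), ("d_fast", "delta_t1"),
    ("f_p", "t1_post"), ("f_p", "delta_t1"),
]


def _fit_mask(subj, config, rng):
    """Liver mask, optionally voxel-subsampled for reduced-scale runs."""
    mask = subj.truth.liver_mask
    if config.voxel_fraction >= 1.0:
        return mask
    idx = np.nonzero(mask.ravel())[0]
    n_keep = max(8, int(round(config.voxel_fraction * idx.size)))
    keep = rng.choice(idx, size=min(n_keep, idx.size), replace=False)
    sub = np.zeros(mask.size, dtype=bool)
    sub[keep] = True
    return sub.reshape(mask.shape)


def subject_ivim_summary(subj, config: PipelineConfig, rng=None):
    """Fit IVIM maps for one subject and summarize over the liver."""
    rng = rng or np.random.Generator(np.random.PCG64(config.seed))
    series = subj.dwi
    if config.median_filter:
        series = median_filter_slicewise(series)
    mask = _fit_mask(subj, config, rng)
    if config.ivim_method == "bayes":
        mcmc = McmcConfig(n_iterations=config.mcmc_iterations,
                          n_burn_in=config.mcmc_burn_in, seed=config.seed)
        maps, _ = fit_ivim_bayes(series, mask, mcmc)
    else:
        maps = fit_ivim_lsq(series, mask, config.b_threshold)
    return maps, global_liver_summary(maps)


def _patient_maps(subj, config: PipelineConfig):
    """T1 pre/post, dT1% and HEF maps for a patient subject."""
    mask = subj.truth.liver_mask
    angles = tuple(sorted(subj.spgr_pre))
    acq_pre = SPGRAcquisition(signals=subj.spgr_pre, flip_angles=angles,
                              tr=subj.spgr_tr, b1_map=subj.b1_field)
    acq_post = SPGRAcquisition(signals=subj.spgr_post, flip_angles=angles,
                               tr=subj.spgr_tr, b1_map=subj.b1_field)
    t1_pre = fit_t1_dfa(acq_pre, mask)
    t1_post = fit_t1_dfa(acq_post, mask)
    delta = delta_t1_percent(t1_pre, t1_post)
    hef = hef_map(subj.dce, config.truncation_fraction, config.split_time)
    return {"t1_pre": t1_pre.t1, "t1_post": t1_post.t1,
            "delta_t1": delta.delta_t1_percent, "hef": hef.hef}


def _roi_slice(mask, requested):
    if requested is not None:
        return int(requested)
    counts = mask.sum(axis=(0, 1))
    return int(np.argmax(counts))  # the best-covered slice


def run_pipeline(subjects, config: PipelineConfig = PipelineConfig()):
    """Run the full analysis over a study bundle; returns the study report."""
    rng = np.random.Generator(np.random.PCG64(config.seed))
    summaries = []
    patient_corr_rows = []
    dice_rows = []
    per_subject_maps = {}
    for subj in subjects:
        maps, summ = subject_ivim_summary(subj, config, rng)
        row = {"subject": subj.subject_id, "cohort": subj.cohort}
        for p in IVIM_PARAMS:
            for stat in ("mean", "median", "sd"):
                row[f"{p}_{stat}"] = summ[p][stat]
        summaries.append(row)
        per_subject_maps[subj.subject_id] = maps

        if subj.cohort == "patient" and subj.dce is not None:
            other_maps = _patient_maps(subj, config)
            ivim_mask = maps.mask
            dce_mask = subj.dce.mask
            dice = dice_similarity(subj.truth.liver_mask, dce_mask)
            dice_rows.append({"subject": subj.subject_id, "dice": dice})
            if dice < config.dice_floor:
                patient_corr_rows.append(
                    {"subject": subj.subject_id, "excluded": True,
                     "reason": f"dice {dice:.3f} below floor "
                               f"{config.dice_floor}"})
                continue
            sl = _roi_slice(subj.truth.liver_mask, config.roi_slice)
            roi2d = subj.truth.liver_mask[:, :, sl] & ivim_mask[:, :, sl]
            fields = {
                "d_slow": maps.d_slow[:, :, sl],
                "d_fast": maps.d_fast[:, :, sl],
                "f_p": maps.f_p[:, :, sl],
                "t1_post": other_maps["t1_post"][:, :, sl],
                "delta_t1": other_maps["delta_t1"][:, :, sl],
                "hef": other_maps["hef"][:, :, sl],
            }
            for a, b in _CORR_PAIRS:
                try:
                    res = voxelwise_pearson(fields[a], fields[b], roi2d)
                except ValueError:
                    continue
                patient_corr_rows.append(
                    {"subject": subj.subject_id, "pair": f"{a}-{b}",
                     "excluded": False, **res})

    summary_df = pd.DataFrame(summaries)
    group_stats, roc_stats = {}, {}
    healthy = summary_df[summary_df.cohort == "healthy"]
    patient = summary_df[summary_df.cohort == "patient"]
    if len(healthy) and len(patient):
        labels = (summary_df.cohort == "patient").astype(int).to_numpy()
        for ip, p in enumerate(IVIM_PARAMS):
            a = healthy[f"{p}_mean"].to_numpy()
            b = patient[f"{p}_mean"].to_numpy()
            cmp_res = mann_whitney_u(a, b, alpha=config.alpha)
            group_stats[p] = {
                "healthy": cmp_res.group_a, "patient": cmp_res.group_b,
                "u": cmp_res.u_statistic, "p_value": cmp_res.p_value,
                "significant": cmp_res.significant,
                "method": cmp_res.method}
            scores = summary_df[f"{p}_mean"].to_numpy()
            roc = roc_analysis(scores, labels)
            # CI on the direction-oriented score so it brackets the
            # reported AUC
            eff = scores if roc.direction == "higher" else -scores
            lo, hi, _ = bootstrap_validate(
                eff, labels, "auc", config.bootstrap_samples,
                config.bootstrap_level,
                seed=config.seed + ip + 1)
            roc_stats[p] = {
                "auc": roc.auc, "direction": roc.direction,
                "cutoff": roc.optimal_cutoff,
                "sensitivity": roc.sensitivity,
                "specificity": roc.specificity,
                "auc_ci": [lo, hi],
                "n_bootstrap": config.bootstrap_samples}

    pooled = {}
    corr_df = pd.DataFrame(patient_corr_rows)
    if len(corr_df) and "pair" in corr_df:
        for pair, grp in corr_df[corr_df.excluded == False].groupby("pair"):
            r_vals = grp["r"].to_numpy()
            r_bar, z_bar = fisher_z_average(r_vals)
            pooled[pair] = {"r_bar": r_bar, "z_bar": z_bar,
                            "min": float(r_vals.min()),
                            "max": float(r_vals.max()),
                            "n_subjects": int(len(r_vals))}

    report = {
        "provenance": {
            "config_hash": config_hash(config),
            "seed": config.seed,
            "version": __version__,
            "config": config.to_dict(),
        },
        "subjects": summaries,
        "group_comparison": group_stats,
        "roc": roc_stats,
        "correlations": patient_corr_rows,
        "pooled_correlations": pooled,
        "dice_qc": dice_rows,
    }
    report["digest"] = report_digest(report)
    return report


def _round_floats(obj, ndigits=10):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (np.floating,)):
        return round(float(obj), ndigits)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def report_digest(report) -> str:
    """Deterministic sha256 digest of a report (provenance+digest excluded)."""
    payload = {k: v for k, v in report.items()
               if k not in ("digest", "provenance")}
    canon = json.dumps(_round_floats(payload), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()
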