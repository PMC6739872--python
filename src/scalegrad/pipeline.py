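"""End-to-end orchestration of the scale-gradient analysis.

Stage order mirrors the analysis: (1) obtain data (synthetic by default),
(2) per-subject GLM with AR(2) prewhitening on percent-signal-change
series, (3) group random effects, (4) scale-sensitive voxel selection
(RM-ANOVA + BH-FDR + cluster threshold), (5) Gaussian tuning fits and
preferred-scale maps, (6) axis profiles and slope permutation tests with
FDR across regions plus the per-subject variant, (7) ROI summaries,
event-related averages and parcellation overlap, (8) geographic
stimulus-scale fit, (9) behavioral correlations, scale ANOVA and the
parametric-modulation GLM. Every threshold, seed and input digest lands
in the machine-readable report.
"""

from __future__ import annotations

import json
import logging
import platform
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, behavior, geo, glm, gradient, roi, synthetic, tuning
from .io import (PipelineConfig, default_affine, table_digest, write_paradigm,
                 write_ratings, write_table, write_volume)

log = logging.getLogger("scalegrad")

N_SCALES = 6


def _setup_logging(out_dir: Path) -> None:
    log.setLevel(logging.INFO)
    if not any(isinstance(h, logging.StreamHandler) for h in log.handlers):
        log.addHandler(logging.StreamHandler())
    fh = logging.FileHandler(out_dir / "pipeline.log", mode="w")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(fh)


def _spawn_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(c.generate_state(1)[0] % (2 ** 31)) for c in ss.spawn(n)]


def simulate_subjects(config: PipelineConfig):
    """Generate the synthetic cohort: per-subject paradigm, ground-truth
    tuning field (gradient region with a linear center drift, control
    region with a flat center) and BOLD runs.

    Yields (subject index, paradigm, field, bold_runs); the true slope of
    the noise-free gradient is attached to the config's synthetic block.
    """
    syn = config.synthetic
    grad_mask = syn.region_mask("gradient")
    ctrl_mask = syn.region_mask("control")
    axis_mm = np.indices(syn.grid_shape)[syn.axis] * syn.voxel_size_mm
    extent = axis_mm[grad_mask].max() - axis_mm[grad_mask].min()
    slope = (N_SCALES - 1) / extent          # centers span 1..6 over the mask

    seeds = _spawn_seeds(config.seed, 4 * syn.n_subjects)
    rng = np.random.default_rng(_spawn_seeds(config.seed + 1, 1)[0])
    noise = synthetic.NoiseSpec(ar=syn.ar, innovation_sd=syn.innovation_sd,
                                drift_amplitude=syn.drift_amplitude,
                                drift_period_s=syn.drift_period_s,
                                baseline=syn.baseline)
    for s in range(syn.n_subjects):
        s_par, s_grad, s_ctrl, s_bold = seeds[4 * s:4 * s + 4]
        paradigm = synthetic.generate_paradigm(
            n_runs=syn.n_runs, blocks_per_run=syn.blocks_per_run, tr=syn.tr,
            seed=s_par)
        subj_slope = slope + rng.normal(0.0, syn.subject_slope_sd)
        grad_field = synthetic.generate_tuning_field(
            syn.grid_shape, grad_mask, axis=syn.axis, slope=subj_slope,
            jitter_sd=syn.jitter_sd, seed=s_grad, amplitude=syn.amplitude,
            width=syn.width, voxel_size_mm=syn.voxel_size_mm)
        ctrl_field = synthetic.generate_tuning_field(
            syn.grid_shape, ctrl_mask, axis=syn.axis, slope=0.0,
            jitter_sd=syn.jitter_sd, seed=s_ctrl, intercept=3.5,
            amplitude=syn.amplitude, width=syn.width,
            voxel_size_mm=syn.voxel_size_mm)
        field = synthetic.merge_fields(grad_field, ctrl_field)
        bold = synthetic.simulate_bold(paradigm, field, noise, seed=s_bold,
                                       hrf_params=config.hrf)
        yield s, paradigm, field, bold


def fit_subject(paradigm, bold_runs, config: PipelineConfig,
                modulation: np.ndarray | None = None):
    """Per-subject GLM: percent signal change, design build, AR(2) fit.

    Returns (beta map (x, y, z, 6), GlmFit, valid-voxel mask).
    """
    shape = bold_runs[0].shape[:3]
    series = np.concatenate([b.reshape(-1, b.shape[-1]) for b in bold_runs],
                            axis=1)
    scaled, valid = glm.percent_signal_change(
        series, min_mean=config.intensity_threshold)
    nuisance = None
    if modulation is not None:
        nuisance = pd.DataFrame({"modulation": modulation})
    design = glm.build_design_matrix(paradigm, nuisance=nuisance,
                                     hrf_params=config.hrf)
    fit = glm.fit_glm_ar2(scaled, design)
    betas = fit.betas_named("scale_").reshape(shape + (N_SCALES,))
    return betas, fit, valid.reshape(shape)


def run_full_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Run every stage on the configured data and write the report.

    Synthetic mode (no input paths configured) generates the cohort from
    the config's study conditions. Returns the report dict; all tables,
    maps and the JSON report are written under ``out_dir``.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_logging(out)
    syn = config.synthetic
    affine = default_affine(syn.voxel_size_mm)
    report: dict = {
        "version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "thresholds": {
            "alpha_voxel": config.alpha_voxel, "r2_gate": config.r2_gate,
            "n_perm": config.n_perm, "cluster_min": config.cluster_min,
            "connectivity": config.connectivity,
            "q_regions": config.q_regions,
            "subject_alpha": config.subject_alpha,
            "intensity_threshold": config.intensity_threshold,
        },
        "warnings": [],
        "stages": {},
    }

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        _run_stages(config, out, affine, report)
    report["warnings"] = sorted({str(w.message) for w in caught})
    report["n_warnings"] = len(caught)
    (out / "report.json").write_text(json.dumps(report, indent=2,
                                                default=_jsonable))
    log.info("pipeline complete; report at %s", out / "report.json")
    return report


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        v = float(obj)
        return v if np.isfinite(v) else None
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, np.bool_):
        return bool(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def _result_row(r) -> dict:
    return {"region": r.region, "method": r.method, "slope": r.slope,
            "intercept": r.intercept, "p": r.p, "q": r.q,
            "significant": r.significant, "n_coords": r.n_coords,
            "n_perm": r.n_perm, "sided": r.sided, "flags": r.flags}


def _run_stages(config: PipelineConfig, out: Path, affine, report: dict):
    syn = config.synthetic
    grad_mask = syn.region_mask("gradient")
    ctrl_mask = syn.region_mask("control")
    regions = {"gradient": grad_mask, "control": ctrl_mask}
    n_vol_run = None

    # stage 1+2: simulate and fit each subject --------------------------------
    log.info("simulating and fitting %d subjects on grid %s",
             syn.n_subjects, syn.grid_shape)
    subject_betas: list[np.ndarray] = []
    era_sums = np.zeros((N_SCALES, config.era_volumes))
    era_n = 0
    region_series: list[np.ndarray] = []   # gradient-region mean PSC series
    paradigms = []
    true_slopes = []
    for s, paradigm, field, bold in simulate_subjects(config):
        n_vol_run = paradigm.volumes_per_run
        betas, fit, valid = fit_subject(paradigm, bold, config)
        subject_betas.append(betas)
        paradigms.append(paradigm)
        # ground truth for the report: OLS slope of true centers on axis mm
        mm = (np.indices(syn.grid_shape)[syn.axis] * syn.voxel_size_mm)
        c = field.center[grad_mask]
        x = mm[grad_mask]
        true_slopes.append(float(np.polyfit(x, c, 1)[0]))
        era_sums += roi.event_related_average(bold, paradigm, grad_mask,
                                              n_volumes=config.era_volumes)
        era_n += 1
        reg_series = np.stack([b[grad_mask].mean(axis=0) for b in bold])
        region_series.append(reg_series.reshape(-1))
        if s == 0:
            write_paradigm(paradigm, out / "paradigm_subject0.tsv")
            write_table(field.truth_frame(), out / "ground_truth_subject0.tsv")
    report["stages"]["simulate"] = {
        "n_subjects": syn.n_subjects, "n_runs": syn.n_runs,
        "volumes_per_run": n_vol_run, "tr": syn.tr,
        "true_slope_scale_per_mm_mean": float(np.mean(true_slopes)),
        "paradigm_digest": table_digest(paradigms[0].to_frame()),
    }

    # stage 3: group random effects ------------------------------------------
    flat = [b.reshape(-1, N_SCALES) for b in subject_betas]
    group = glm.group_random_effects(flat,
                                     names=[f"scale_{i}" for i in range(1, 7)])
    group_mean = group.mean.reshape(syn.grid_shape + (N_SCALES,))
    report["stages"]["group_glm"] = {"n_subjects": group.n}

    # stage 4: scale-sensitive voxel selection -------------------------------
    sel = tuning.select_scale_sensitive(
        subject_betas, np.ones(syn.grid_shape, dtype=bool),
        alpha=config.alpha_voxel, cluster_min=config.cluster_min,
        connectivity=config.connectivity)
    n_selected = int(sel.selected.sum())
    log.info("selected %d scale-sensitive voxels (FDR q<%g, cluster>=%d)",
             n_selected, config.alpha_voxel, config.cluster_min)
    report["stages"]["selection"] = {
        "n_tested": int(np.isfinite(sel.p).sum()),
        "n_selected": n_selected,
        "n_clusters": int(sel.cluster_labels.max()),
        "sensitivity_gradient": float(
            sel.selected[grad_mask].mean()),
        "false_positive_rate_outside": float(
            sel.selected[~(grad_mask | ctrl_mask)].mean()),
    }
    write_volume(sel.selected.astype(np.int16), affine,
                 out / "selected_mask.nii")

    # stage 5: Gaussian tuning on group betas of selected voxels -------------
    sel_idx = np.flatnonzero(sel.selected.ravel())
    fits = tuning.fit_gaussian_tuning_map(
        group_mean.reshape(-1, N_SCALES)[sel_idx], r2_gate=config.r2_gate)
    peak_map = np.full(syn.grid_shape, np.nan)
    max_map = np.full(syn.grid_shape, np.nan)
    gated = fits["passes_gate"]
    peak_flat = np.where(gated, fits["peak_scale"], np.nan)
    peak_map.ravel()[sel_idx] = peak_flat
    max_map.ravel()[sel_idx] = fits["max_scale"]
    write_volume(np.nan_to_num(peak_map), affine, out / "peak_scale.nii")
    write_volume(np.nan_to_num(max_map), affine, out / "max_scale.nii")
    tuning_table = pd.DataFrame({
        "voxel": sel_idx, "F": sel.F.ravel()[sel_idx],
        "p": sel.p.ravel()[sel_idx], "q": sel.q.ravel()[sel_idx],
        "amplitude": fits["amplitude"], "center": fits["center"],
        "width": fits["width"], "r2": fits["r2"],
        "peak_scale": fits["peak_scale"], "max_scale": fits["max_scale"],
        "passes_gate": fits["passes_gate"].astype(int),
    })
    write_table(tuning_table, out / "voxel_tuning.tsv")
    report["stages"]["tuning"] = {
        "n_fit": len(sel_idx),
        "n_gated": int(gated.sum()),
        "gate_rate": float(gated.mean()) if len(sel_idx) else None,
    }

    # stage 6: gradients ------------------------------------------------------
    perm_seeds = _spawn_seeds(config.seed + 2, 2 * len(regions) + 1)
    results = {"peak": [], "max": []}
    profiles_rows = []
    for i, (name, mask) in enumerate(regions.items()):
        for j, (method, vol) in enumerate([("peak", peak_map),
                                           ("max", max_map)]):
            prof = gradient.axis_profile(vol, mask, axis=syn.axis,
                                         method=method, region_name=name)
            res = gradient.permutation_test_slope(
                prof, n_perm=config.n_perm, seed=perm_seeds[2 * i + j])
            results[method].append(res)
            for c, m, k in zip(prof.coords, prof.mean_scale, prof.counts):
                profiles_rows.append((name, method, c, m, k))
    for method in results:
        gradient.fdr_across_regions(results[method], q=config.q_regions)
    write_table(pd.DataFrame(profiles_rows,
                             columns=["region", "method", "coord",
                                      "mean_scale", "n_voxels"]),
                out / "axis_profiles.tsv")
    grad_rows = [_result_row(r) for m in results for r in results[m]]
    write_table(pd.DataFrame(grad_rows), out / "gradient_tests.tsv")
    report["stages"]["gradients"] = grad_rows

    if config.run_subject_level:
        subj_results, n_sig = gradient.subject_level_gradient(
            subject_betas, grad_mask, axis=syn.axis, n_perm=config.n_perm,
            seed=perm_seeds[-1], r2_gate=config.r2_gate,
            alpha=config.subject_alpha)
        report["stages"]["subject_gradients"] = {
            "n_subjects": len(subj_results),
            "n_significant": n_sig,
            "p_values": [r.p for r in subj_results],
        }
        log.info("subject-level gradient: %d of %d subjects significant",
                 n_sig, len(subj_results))

    # stage 7: ROI summaries, ERA, parcellation overlap ----------------------
    roi_rows = []
    for name, mask in regions.items():
        summary = roi.roi_betas(subject_betas, mask, region_name=name)
        for s in range(N_SCALES):
            roi_rows.append((name, s + 1, summary.mean[s], summary.se[s],
                             summary.n))
    write_table(pd.DataFrame(roi_rows, columns=["region", "scale",
                                                "mean_beta", "se", "n"]),
                out / "roi_betas.tsv")
    era = era_sums / era_n
    era_frame = pd.DataFrame(era.T, columns=[f"scale_{i}"
                                             for i in range(1, 7)])
    era_frame.insert(0, "volume", np.arange(config.era_volumes))
    write_table(era_frame, out / "event_related_average.tsv")

    # synthetic 7-label parcellation: equal bands along the gradient axis
    parc = (np.indices(syn.grid_shape)[syn.axis]
            * 7 // syn.grid_shape[syn.axis]) + 1
    overlap = roi.network_overlap(sel.selected, parc)
    write_table(overlap, out / "network_overlap.tsv")
    report["stages"]["roi"] = {
        "regions": list(regions),
        "era_volumes": config.era_volumes,
        "overlap_top_label": int(
            overlap.loc[overlap["percent"].idxmax(), "label"]),
    }

    # stage 8: geographic scale analysis -------------------------------------
    geo_seed = _spawn_seeds(config.seed + 3, 1)[0]
    stimuli = synthetic.generate_geo_stimuli(seed=geo_seed)
    write_table(stimuli, out / "geo_stimuli.tsv")
    dists = geo.pairwise_distances(stimuli)
    geo_fit = geo.log_scale_fit(dists)
    write_table(geo_fit.per_scale, out / "geo_scale_distances.tsv")
    report["stages"]["geo"] = {
        "slope_log10km_per_scale": geo_fit.slope,
        "intercept": geo_fit.intercept, "r2": geo_fit.r2,
        "mode": geo_fit.mode,
        "stimuli_digest": table_digest(stimuli),
    }

    # stage 9: behavioral ratings and parametric modulation ------------------
    beh_seed = _spawn_seeds(config.seed + 4, 1)[0]
    n_raters = max(syn.rating_subjects, syn.n_subjects)
    ratings = synthetic.generate_ratings(n_subjects=n_raters, seed=beh_seed)
    write_ratings(ratings, out / "ratings_location.tsv",
                  out / "ratings_scale.tsv")
    beh_rows = []
    for measure in ["familiarity", "difficulty", "first_person",
                    "third_person"]:
        rc = behavior.correlate_with_scale(ratings, measure)
        beh_rows.append((measure, rc.mean_r, rc.t, rc.p, rc.df,
                         rc.n_excluded))
    beh_frame = pd.DataFrame(beh_rows, columns=["measure", "mean_r", "t",
                                                "p", "df", "n_excluded"])
    write_table(beh_frame, out / "behavior_correlations.tsv")
    aov = behavior.anova_scales(ratings, "familiarity", alpha=0.01)
    write_table(aov["pairwise"], out / "behavior_tukey_familiarity.tsv")

    # modulation GLM on the gradient-region mean series, per subject
    mod_betas = []
    for s, paradigm in enumerate(paradigms):
        weights = glm.modulation_weights_from_ratings(paradigm, ratings, s,
                                                      "familiarity")
        col = glm.build_modulation_regressor(paradigm, weights,
                                             hrf_params=config.hrf)
        design = glm.build_design_matrix(
            paradigm, nuisance=pd.DataFrame({"mod_familiarity": col}),
            hrf_params=config.hrf)
        fit = glm.fit_glm_ar2(region_series[s][None, :], design)
        mod_betas.append(fit.beta[0, design.names.index("mod_familiarity")])
    mod = glm.contrast(np.array(mod_betas)[:, None], np.array([1.0]))
    report["stages"]["behavior"] = {
        "correlations": beh_rows,
        "anova_F": aov["F"], "anova_p": aov["p"],
        "modulation_t": float(mod["t"]), "modulation_p": float(mod["p"]),
    }

    # headline qualitative outcome -------------------------------------------
    peak_res = {r.region: r for r in results["peak"]}
    report["outcome"] = {
        "gradient_significant": bool(peak_res["gradient"].significant),
        "gradient_slope_scale_per_mm":
            peak_res["gradient"].slope / syn.voxel_size_mm,
        "gradient_p": peak_res["gradient"].p,
        "control_significant": bool(peak_res["control"].significant),
        "control_p": peak_res["control"].p,
    }
    log.info("gradient region: slope %.4f scale/coord, p=%.4g, "
             "significant=%s", peak_res["gradient"].slope,
             peak_res["gradient"].p, peak_res["gradient"].significant)
    log.info("control region: p=%.4g, significant=%s",
             peak_res["control"].p, peak_res["control"].significant)
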