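"""Desk-scale validation experiments.

The patient scans behind the original reference-region comparison are not
public, so validation is property- and simulation-based: each experiment here
regenerates synthetic data under the study conditions, runs the pipeline, and
returns the summary quantities the test suite and the reproduction script
assert on.  Problem sizes (regions per scan, subjects per cohort, replicate
counts) are chosen so the whole battery runs in minutes on one CPU.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .kinetic_models import dvr_from_vt, fit_2t4k_vb, fit_srtm, rlogan_dvr
from .pipeline import PipelineConfig, run_compare, run_quantify, sessions_metadata
from .synthetic_cohort import (
    CohortScenario,
    default_reference_profiles,
    default_schedule,
    generate_longitudinal_cohort,
    generate_scan,
    generate_trt_cohort,
    make_input_function,
    simulate_profile,
    target_profile,
)


def _study_profiles(n_targets: int = 19, model: str = "2T4K", vb: float | None = None):
    profiles = list(default_reference_profiles().values())
    rng = np.random.default_rng(1234)
    dvrs = np.concatenate([
        rng.uniform(0.95, 1.2, n_targets // 2),
        rng.uniform(1.5, 2.5, n_targets - n_targets // 2),
    ])
    for i, dvr in enumerate(dvrs):
        profiles.append(target_profile(f"ctx_{i:02d}", float(dvr), model=model))
    if vb is not None:
        profiles = [replace(p, Vb=vb) if not p.components else p for p in profiles]
    return profiles


def vt_recovery(seed: int, n_noise_replicates: int = 50, noise_level: float = 0.05) -> dict:
    """Plasma-input gold standard recovery.

    Noise-free: fit every region of a full synthetic scan and compare V_T and
    GMCB-referenced DVR with the generating truth.  Noisy: refit one
    mid-burden target across independent noise replicates and take the median
    absolute V_T error.
    """
    fn, _ = make_input_function()
    schedule = default_schedule()
    profiles = _study_profiles(n_targets=19)
    session, truth = generate_scan(profiles, fn, schedule, noise_level=0.0, seed=seed)
    tt = truth.set_index("region")
    vt_err, vt_est = {}, {}
    for region, tac in session.tacs.items():
        params, _ = fit_2t4k_vb(tac, fn, seed=seed)
        vt_est[region] = params.VT
        vt_err[region] = abs(params.VT / tt.loc[region, "VT_true"] - 1.0)
    dvr_err = {
        r: abs(
            dvr_from_vt(vt_est[r], vt_est["GMCB"]) / tt.loc[r, "DVR_true"] - 1.0
        )
        for r in session.tacs
        if r != "GMCB"
    }
    noisy_profile = target_profile("noisy", 2.0)
    clean = simulate_profile(noisy_profile, fn, schedule)
    from .synthetic_cohort import add_tac_noise

    noisy_errs = []
    rng = np.random.default_rng(seed)
    for _ in range(n_noise_replicates):
        tac = add_tac_noise(clean, noise_level, int(rng.integers(2**31)))
        params, _ = fit_2t4k_vb(tac, fn, seed=int(rng.integers(2**31)))
        noisy_errs.append(abs(params.VT / noisy_profile.vt - 1.0))
    return {
        "max_vt_err": max(vt_err.values()),
        "max_dvr_err": max(dvr_err.values()),
        "median_noisy_vt_err": float(np.median(noisy_errs)),
        "n_regions": len(vt_err),
        "n_replicates": n_noise_replicates,
    }


DVR_GRID = (1.0, 1.25, 1.5, 2.0, 2.5, 3.0)


def reference_method_validity(seed: int) -> dict:
    """Reference Logan and SRTM on ideal scans (one-tissue, no blood volume)."""
    fn, _ = make_input_function()
    schedule = default_schedule()
    ref = simulate_profile(
        replace(default_reference_profiles()["GMCB"], Vb=0.0), fn, schedule
    )
    rl, sr = [], []
    for dvr in DVR_GRID:
        profile = replace(target_profile("t", dvr, model="1T"), Vb=0.0)
        tac = simulate_profile(profile, fn, schedule)
        rl.append(rlogan_dvr(tac, ref).DVR)
        sr.append(fit_srtm(tac, ref, seed=seed)[0].DVR)
    grid = np.asarray(DVR_GRID)
    return {
        "rlogan_max_err": float(np.max(np.abs(np.asarray(rl) / grid - 1.0))),
        "srtm_max_err": float(np.max(np.abs(np.asarray(sr) / grid - 1.0))),
        "rlogan_r": float(np.corrcoef(grid, rl)[0, 1]),
        "srtm_r": float(np.corrcoef(grid, sr)[0, 1]),
        "n": len(DVR_GRID),
    }


def trt_noise_ordering(seed: int, levels=(0.02, 0.10), n_per_group: int = 10) -> dict:
    """Median composite TRT variability per noise level (fast methods only)."""
    cfg = PipelineConfig(
        methods=("DVR_RLOGAN", "SUVR_40_60", "SUVR_60_90"), include_reference_suv=False
    )
    medians = {}
    for level in levels:
        scenario = CohortScenario(
            n_pos=n_per_group, n_neg=n_per_group, n_targets=3, trt=True,
            noise_level=level, seed=seed,
        )
        sessions, _ = generate_trt_cohort(scenario)
        table = run_quantify(sessions, cfg)
        report = run_compare(table, sessions_metadata(sessions), cfg)
        medians[level] = float(report.trt["median_trt_pct"].median())
    return {"median_trt_by_level": medians, "n_subjects": 2 * n_per_group}


def drift_stability(seed: int, n_per_group: int = 9, drift: float = -2.0) -> dict:
    """Longitudinal reference-region SUV stability with brainstem drift.

    Returns Bonferroni-adjusted paired-t p-values per reference region for the
    60-90 min window at the given annual white-matter drift.
    """
    scenario = CohortScenario(
        n_pos=n_per_group, n_neg=n_per_group, n_targets=1, longitudinal=True,
        noise_level=0.05, wm_drift_pct_per_year=drift, seed=seed,
    )
    sessions, _ = generate_longitudinal_cohort(scenario)
    cfg = PipelineConfig(methods=(), include_reference_suv=True)
    table = run_quantify(sessions, cfg)
    report = run_compare(table, sessions_metadata(sessions), cfg)
    late = report.stability[report.stability["method"] == "SUV_60_90"]
    return {
        "p_adjusted": dict(zip(late["region"], late["p_adjusted"])),
        "n_subjects": 2 * n_per_group,
    }


def accumulation_model_preference(
    seeds, n_per_group: int = 15, references=("GMCB", "WCB")
) -> dict:
    """Fraction of seeds in which quadratic beats linear (AIC) for the
    baseline-burden vs annual-change relationship, per reference region."""
    cfg = PipelineConfig(
        methods=("DVR_RLOGAN",),
        reference_regions=tuple(references),
        include_reference_suv=False,
    )
    wins = {ref: 0 for ref in references}
    for seed in seeds:
        scenario = CohortScenario(
            n_pos=n_per_group, n_neg=n_per_group, n_targets=4, longitudinal=True,
            noise_level=0.05, seed=int(seed),
        )
        sessions, _ = generate_longitudinal_cohort(scenario)
        table = run_quantify(sessions, cfg)
        report = run_compare(table, sessions_metadata(sessions), cfg)
        sel = report.model_selection.set_index("reference_region")
        for ref in references:
            if sel.loc[ref, "preferred"] == "quadratic":
                wins[ref] += 1
    n = len(list(seeds))
    return {
        "quadratic_fraction": {ref: wins[ref] / n for ref in references},
        "n_seeds": n,
        "n_subjects": 2 * n_per_group,
    }
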