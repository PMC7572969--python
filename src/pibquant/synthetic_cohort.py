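"""Synthetic dynamic-PiB cohorts with known ground truth.

The study design being emulated: 90-min dynamic scans with a metabolite-
corrected arterial input, ~19 cortical target regions, and five candidate
reference regions -- cerebellar grey (GMCB, the validated reference), whole
cerebellum (WCB), white-matter brainstem/pons (WMBS), whole brainstem (WBS)
and eroded subcortical white matter (WMES).  Grey-matter references are
modelled as fast one-tissue kinetics; white-matter regions get lower K1,
slower washout and a higher nonspecific distribution volume, which is exactly
the violation of reference-tissue similarity that biases reference methods
low against the plasma-input gold standard.  Mixed regions (WCB, WBS) are
volume-weighted mixtures of a grey and a white component, making the
grey/white contrast mechanistically explicit.

Cohort generators produce test-retest replicates (identical generating
parameters, independent noise) and longitudinal baseline/follow-up pairs
with an inverted-U amyloid accumulation law (annual change maximal at
mid-range baseline burden) and an optional multiplicative white-matter SUV
drift (a slow annual decline of brainstem K1, dragging V_T and late-window
SUV down together).  Every generator is deterministic given its scenario seed,
and each scan ships with a sidecar truth table (true V_T and DVR vs GMCB).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .blood_input import CorrectionModel, InputFunction, default_grid, derive_plasma_input
from .kinetic_models import KineticParams2T4K, simulate_2t4k
from .tac_core import (
    DEFAULT_TARGET_REGIONS,
    REFERENCE_REGIONS,
    FrameSchedule,
    ScanSession,
    TimeActivityCurve,
)

#: Default 90-min / 20-frame schedule: 4x0.25, 4x1, 2x2.5, 4x5, 6x10 min.
DEFAULT_FRAME_DURATIONS = (0.25,) * 4 + (1.0,) * 4 + (2.5,) * 2 + (5.0,) * 4 + (10.0,) * 6


def default_schedule() -> FrameSchedule:
    durs = np.array(DEFAULT_FRAME_DURATIONS)
    starts = np.concatenate(([0.0], np.cumsum(durs)[:-1]))
    return FrameSchedule(starts, durs)


#: Plausible region volumes (mL) for volume-weighted composites.
DEFAULT_VOLUMES = {
    "GMCB": 60.0,
    "WCB": 130.0,
    "WMBS": 12.0,
    "WBS": 30.0,
    "WMES": 150.0,
}
_TARGET_VOLUMES = (22.0, 14.0, 30.0, 18.0, 24.0, 16.0, 12.0, 8.0, 10.0, 9.0,
                   28.0, 20.0, 6.0, 21.0, 34.0, 26.0, 23.0, 17.0, 32.0)
for _name, _vol in zip(DEFAULT_TARGET_REGIONS, _TARGET_VOLUMES):
    DEFAULT_VOLUMES[_name] = _vol

GMCB_K1 = 0.30  # mL cm^-3 min^-1
GMCB_K2 = 0.15  # min^-1
GMCB_VT = GMCB_K1 / GMCB_K2  # 2.0 mL/cm^3
DEFAULT_VB = 0.05


class ScenarioError(ValueError):
    """A cohort scenario is inconsistent or incomplete."""


# ---------------------------------------------------------------------------
# kinetic profiles


@dataclass(frozen=True)
class RegionKineticsProfile:
    """Generating kinetics of one region: simple micro-parameters or a mixture.

    ``model`` is "2T4K" or "1T" (one-tissue, i.e. k3 = 0, SRTM-consistent).
    A mixture region holds weighted component profiles and is simulated as the
    volume-weighted sum of its component TACs; its true V_T is the weighted
    mean of component V_Ts (exact, since V_T is linear in tissue fractions).
    """

    region_label: str
    tissue_class: str = "grey"  # grey | white | mixed
    K1: float | None = None
    k2: float | None = None
    k3: float = 0.0
    k4: float = 0.03
    Vb: float = DEFAULT_VB
    components: tuple[tuple["RegionKineticsProfile", float], ...] = ()

    @property
    def model(self) -> str:
        if self.components:
            return "mixture"
        return "1T" if self.k3 == 0 else "2T4K"

    @property
    def vt(self) -> float:
        if self.components:
            wsum = sum(w for _, w in self.components)
            return sum(p.vt * w for p, w in self.components) / wsum
        return KineticParams2T4K(self.K1, self.k2, self.k3, self.k4, self.Vb).VT

    def params(self) -> KineticParams2T4K:
        if self.components:
            raise ScenarioError("mixture profiles have no single parameter set")
        return KineticParams2T4K(self.K1, self.k2, self.k3, self.k4, self.Vb)

    def scale_uptake(self, factor: float) -> "RegionKineticsProfile":
        """Scale K1 (k2 untouched): uptake amplitude and V_T drift together.

        This is the white-matter drift mechanism -- a slow loss of nonspecific
        tracer delivery/retention that lowers late-window SUV.  Scaling k2 in
        compensation would leave V_T fixed but barely move the 60-90 min SUV,
        because slow white matter is already near equilibrium there.
        """
        if self.components:
            comps = tuple((p.scale_uptake(factor), w) for p, w in self.components)
            return replace(self, components=comps)
        return replace(self, K1=self.K1 * factor)


def default_reference_profiles() -> dict[str, RegionKineticsProfile]:
    """The five reference regions with grey/white/mixed kinetics."""
    gmcb = RegionKineticsProfile("GMCB", "grey", K1=GMCB_K1, k2=GMCB_K2)
    cereb_wm = RegionKineticsProfile("cerebellar_wm", "white", K1=0.10, k2=0.040)
    wmbs = RegionKineticsProfile("WMBS", "white", K1=0.10, k2=0.037)
    bs_grey = RegionKineticsProfile("brainstem_grey", "grey", K1=0.28, k2=0.14)
    wmes = RegionKineticsProfile("WMES", "white", K1=0.09, k2=0.030)
    wcb = RegionKineticsProfile(
        "WCB", "mixed", components=((gmcb, 0.7), (cereb_wm, 0.3))
    )
    wbs = RegionKineticsProfile(
        "WBS", "mixed", components=((wmbs, 0.7), (bs_grey, 0.3))
    )
    return {"GMCB": gmcb, "WCB": wcb, "WMBS": wmbs, "WBS": wbs, "WMES": wmes}


def target_profile(label: str, dvr: float, model: str = "2T4K", k4: float = 0.03) -> RegionKineticsProfile:
    """Target-region profile with a prescribed true DVR against GMCB.

    2T4K: K1/k2 matches GMCB V_T and specific binding enters through
    k3 = k4 (DVR - 1); below DVR = 1 the nondisplaceable pool shrinks instead.
    1T: pure one-tissue with K1/k2 = DVR * V_T(GMCB) via slower washout
    (SRTM-consistent by construction).
    """
    if dvr <= 0:
        raise ScenarioError("DVR must be positive")
    if model == "1T":
        return RegionKineticsProfile(label, "grey", K1=GMCB_K1, k2=GMCB_K2 / dvr)
    if model != "2T4K":
        raise ScenarioError(f"unknown target model {model!r}")
    if dvr <= 1.0:
        return RegionKineticsProfile(label, "grey", K1=GMCB_K1 * dvr, k2=GMCB_K2)
    return RegionKineticsProfile(
        label, "grey", K1=GMCB_K1, k2=GMCB_K2, k3=k4 * (dvr - 1.0), k4=k4
    )


# ---------------------------------------------------------------------------
# blood data


def feng_plasma_input(
    A1: float = 200.0,
    A2: float = 5.0,
    A3: float = 4.0,
    l1: float = -4.0,
    l2: float = -0.12,
    l3: float = -0.01,
    delay: float = 0.5,
    grid: np.ndarray | None = None,
) -> np.ndarray:
    """Feng-type arterial plasma curve (kBq/mL) on the grid.

    C_p(t') = (A1 t' - A2 - A3) e^{l1 t'} + A2 e^{l2 t'} + A3 e^{l3 t'} for
    t' = t - delay > 0, else 0: a sharp early peak with bi-exponential tail.
    """
    if not l1 < l2 < l3 < 0:
        raise ScenarioError("need l1 < l2 < l3 < 0")
    if delay < 0:
        raise ScenarioError("delay must be >= 0")
    if grid is None:
        grid = default_grid(90.0)
    tp = np.asarray(grid, dtype=float) - delay
    cp = np.where(
        tp > 0,
        (A1 * tp - A2 - A3) * np.exp(l1 * tp) + A2 * np.exp(l2 * tp) + A3 * np.exp(l3 * tp),
        0.0,
    )
    if np.any(cp < 0):
        raise ScenarioError("Feng parameters yield negative plasma concentrations")
    return cp


def default_corrections(grid: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(plasma/whole-blood ratio, parent fraction) sampled on the grid.

    The parent fraction falls exponentially from 1 towards a 0.15 plateau
    (tau = 20 min), emulating rapid PiB metabolism; the plasma/whole-blood
    ratio rises slowly above 1.
    """
    g = np.asarray(grid, dtype=float)
    ratio = 1.05 + 0.0005 * g
    pf = 0.15 + 0.85 * np.exp(-g / 20.0)
    return ratio, pf


def make_input_function(
    grid: np.ndarray | None = None, amplitude: float = 1.0
) -> tuple[InputFunction, CorrectionModel]:
    """Build a synthetic InputFunction plus the corrections that reproduce it.

    The Feng curve is taken as the metabolite-corrected plasma parent; the
    whole-blood curve is derived through the inverse corrections, so feeding
    the emitted whole-blood samples and corrections back through
    ``derive_plasma_input`` recovers the parent curve exactly.
    """
    if grid is None:
        grid = default_grid(90.0)
    cp = amplitude * feng_plasma_input(grid=grid)
    ratio, pf = default_corrections(grid)
    wb = cp / (ratio * np.maximum(pf, 1e-12))
    wb[0] = 0.0
    corrections = CorrectionModel.from_tables(grid, ratio, pf)
    fn = derive_plasma_input(np.column_stack([grid, wb]), corrections, grid)
    return fn, corrections


# ---------------------------------------------------------------------------
# noise


def add_tac_noise(
    tac: TimeActivityCurve,
    level: float,
    seed: "int | np.random.Generator",
    floor_frac: float = 0.05,
) -> TimeActivityCurve:
    """Gaussian TAC noise with duration-scaled SD.

    sigma_i = level * max(value_i, floor) / sqrt(duration_i), with
    floor = floor_frac * max(values) so early near-zero frames still get a
    realistic noise floor.  level 0 returns the TAC unchanged.
    """
    if level < 0:
        raise ScenarioError("noise level must be >= 0")
    if level == 0:
        return tac
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    floor = floor_frac * float(np.max(np.abs(tac.values))) if tac.values.size else 0.0
    sigma = level * np.maximum(np.abs(tac.values), floor) / np.sqrt(tac.schedule.durations)
    return tac.with_values(tac.values + rng.normal(0.0, 1.0, tac.values.shape) * sigma)


# ---------------------------------------------------------------------------
# scan generation


def simulate_profile(
    profile: RegionKineticsProfile,
    input_function: InputFunction,
    schedule: FrameSchedule,
) -> TimeActivityCurve:
    if profile.components:
        wsum = sum(w for _, w in profile.components)
        vals = sum(
            (w / wsum) * simulate_profile(p, input_function, schedule).values
            for p, w in profile.components
        )
        return TimeActivityCurve(
            schedule, vals, region_label=profile.region_label,
            volume_ml=DEFAULT_VOLUMES.get(profile.region_label),
        )
    tac = simulate_2t4k(profile.params(), input_function, schedule)
    return TimeActivityCurve(
        schedule, tac.values, region_label=profile.region_label,
        volume_ml=DEFAULT_VOLUMES.get(profile.region_label),
    )


def generate_scan(
    profiles: Sequence[RegionKineticsProfile],
    input_function: InputFunction,
    schedule: FrameSchedule,
    noise_level: float = 0.0,
    seed: int = 0,
    subject_id: str = "sim",
    scan_id: str = "scan",
    scan_role: str = "test",
    **session_kwargs,
) -> tuple[ScanSession, pd.DataFrame]:
    """Simulate one scan from kinetic profiles; returns (session, truth table)."""
    labels = [p.region_label for p in profiles]
    missing = set(REFERENCE_REGIONS) - set(labels)
    if missing:
        raise ScenarioError(f"profiles must include all reference regions; missing {sorted(missing)}")
    if len(labels) <= len(REFERENCE_REGIONS):
        raise ScenarioError("profiles must include at least one target region")
    vt_gmcb = next(p for p in profiles if p.region_label == "GMCB").vt
    rng = np.random.default_rng(seed)
    tacs: dict[str, TimeActivityCurve] = {}
    truth_rows = []
    for profile in profiles:
        clean = simulate_profile(profile, input_function, schedule)
        tacs[profile.region_label] = add_tac_noise(clean, noise_level, rng)
        simple = not profile.components
        truth_rows.append(
            {
                "subject_id": subject_id,
                "scan_id": scan_id,
                "region": profile.region_label,
                "model": profile.model,
                "K1": profile.K1 if simple else np.nan,
                "k2": profile.k2 if simple else np.nan,
                "k3": profile.k3 if simple else np.nan,
                "k4": profile.k4 if simple else np.nan,
                "Vb": profile.Vb if simple else np.nan,
                "VT_true": profile.vt,
                "DVR_true": profile.vt / vt_gmcb,
            }
        )
    session = ScanSession(
        subject_id=subject_id,
        scan_id=scan_id,
        scan_role=scan_role,
        tacs=tacs,
        input_function=input_function,
        **session_kwargs,
    )
    return session, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# cohort scenarios


@dataclass
class CohortScenario:
    """Conditions of a synthetic cohort; the defaults are the study conditions.

    Group DVR ranges (amyloid-positive 1.8-2.5, negative 0.95-1.2) and 5%
    fractional TAC noise define the cross-sectional design; the longitudinal
    design draws baseline burden across the whole continuum, follow-up
    intervals from a truncated normal around 2.6 y, and applies an inverted-U
    accumulation law plus an optional white-matter drift.
    """

    n_pos: int = 10
    n_neg: int = 10
    dvr_range_pos: tuple[float, float] = (1.8, 2.5)
    dvr_range_neg: tuple[float, float] = (0.95, 1.2)
    noise_level: float = 0.05
    n_targets: int = len(DEFAULT_TARGET_REGIONS)
    target_model: str = "2T4K"  # 2T4K | 1T
    trt: bool = False
    longitudinal: bool = False
    followup_years_mean: float = 2.6
    followup_years_sd: float = 0.45
    followup_years_min: float = 1.9
    followup_years_max: float = 4.0
    baseline_span: tuple[float, float] = (1.0, 2.5)
    accumulation_max_pct: float = 5.0  # peak annual DVR change (%/y)
    accumulation_peak_dvr: float = 1.75
    accumulation_width: float = 0.4
    wm_drift_pct_per_year: float = 0.0  # applied to WBS + WMBS K1 (and k2)
    visual_threshold_dvr: float = 1.4
    input_amplitude_sd: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos < 1 or self.n_neg < 1:
            raise ScenarioError("group sizes must be >= 1")
        if self.noise_level < 0:
            raise ScenarioError("noise level must be >= 0")
        if not 1 <= self.n_targets <= len(DEFAULT_TARGET_REGIONS):
            raise ScenarioError(f"n_targets must be 1..{len(DEFAULT_TARGET_REGIONS)}")

    @property
    def target_regions(self) -> tuple[str, ...]:
        return DEFAULT_TARGET_REGIONS[: self.n_targets]

    @staticmethod
    def from_dict(d: Mapping) -> "CohortScenario":
        d = dict(d)
        for key in ("dvr_range_pos", "dvr_range_neg", "baseline_span"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return CohortScenario(**d)

    @staticmethod
    def from_yaml(path: str | Path) -> "CohortScenario":
        return CohortScenario.from_dict(yaml.safe_load(Path(path).read_text()))


def accumulation_rate(scenario: CohortScenario, baseline_dvr: float) -> float:
    """Annual % DVR change as an inverted-U function of baseline burden."""
    z = (baseline_dvr - scenario.accumulation_peak_dvr) / scenario.accumulation_width
    return scenario.accumulation_max_pct * float(np.exp(-0.5 * z * z))


def _truncnorm(rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float) -> float:
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(np.clip(mean, lo, hi))


def _subject_profiles(
    scenario: CohortScenario, target_dvrs: np.ndarray
) -> list[RegionKineticsProfile]:
    refs = default_reference_profiles()
    profiles = [refs[r] for r in REFERENCE_REGIONS]
    for label, dvr in zip(scenario.target_regions, target_dvrs):
        profiles.append(target_profile(label, float(dvr), model=scenario.target_model))
    return profiles


def generate_trt_cohort(
    scenario: CohortScenario,
) -> tuple[list[ScanSession], pd.DataFrame]:
    """Test-retest cohort: per subject two scans, same kinetics, independent noise."""
    if not scenario.trt:
        raise ScenarioError("scenario.trt must be set for a TRT cohort")
    rng = np.random.default_rng(scenario.seed)
    sessions: list[ScanSession] = []
    truths: list[pd.DataFrame] = []
    groups = ["negative"] * scenario.n_neg + ["positive"] * scenario.n_pos
    for i, group in enumerate(groups):
        subject = f"trt{i + 1:03d}"
        lo, hi = scenario.dvr_range_neg if group == "negative" else scenario.dvr_range_pos
        dvrs = rng.uniform(lo, hi, size=scenario.n_targets)
        profiles = _subject_profiles(scenario, dvrs)
        amp = float(np.exp(rng.normal(0.0, scenario.input_amplitude_sd)))
        weight = float(np.clip(rng.normal(75.0, 10.0), 50.0, 110.0))
        for role in ("test", "retest"):
            dose = float(np.clip(rng.normal(370.0, 30.0), 300.0, 440.0))
            # plasma amplitude scales with dose per unit body mass
            input_fn, _ = make_input_function(
                amplitude=amp * (dose / 370.0) * (75.0 / weight)
            )
            noise_seed = int(rng.integers(2**31))
            session, truth = generate_scan(
                profiles,
                input_fn,
                default_schedule(),
                noise_level=scenario.noise_level,
                seed=noise_seed,
                subject_id=subject,
                scan_id=f"{subject}_{role}",
                scan_role=role,
                injected_dose_MBq=dose,
                weight_kg=weight,
                visual_status=group,
            )
            sessions.append(session)
            truths.append(truth)
    return sessions, pd.concat(truths, ignore_index=True)


def generate_longitudinal_cohort(
    scenario: CohortScenario,
) -> tuple[list[ScanSession], pd.DataFrame]:
    """Baseline/follow-up cohort with inverted-U accumulation and optional WM drift.

    No arterial data are attached (plasma-input fits are not available for the
    longitudinal design); dose and weight are attached so SUVs are computable.
    """
    if not scenario.longitudinal:
        raise ScenarioError("scenario.longitudinal must be set for a longitudinal cohort")
    rng = np.random.default_rng(scenario.seed)
    n = scenario.n_pos + scenario.n_neg
    sessions: list[ScanSession] = []
    truths: list[pd.DataFrame] = []
    lo, hi = scenario.baseline_span
    for i in range(n):
        subject = f"lng{i + 1:03d}"
        burden = lo + (hi - lo) * (i + 0.5) / n  # even coverage of the continuum
        jitter = rng.uniform(0.92, 1.08, size=scenario.n_targets)
        dvrs_bl = np.maximum(burden * jitter, 0.9)
        status = "positive" if burden >= scenario.visual_threshold_dvr else "negative"
        years = _truncnorm(
            rng,
            scenario.followup_years_mean,
            scenario.followup_years_sd,
            scenario.followup_years_min,
            scenario.followup_years_max,
        )
        rate = accumulation_rate(scenario, float(burden))
        dvrs_fu = dvrs_bl * (1.0 + rate / 100.0 * years)
        weight = float(np.clip(rng.normal(75.0, 10.0), 50.0, 110.0))
        amp = float(np.exp(rng.normal(0.0, scenario.input_amplitude_sd)))
        drift = scenario.wm_drift_pct_per_year
        for role, dvrs in (("baseline", dvrs_bl), ("followup", dvrs_fu)):
            profiles = _subject_profiles(scenario, dvrs)
            if role == "followup" and drift != 0.0:
                factor = (1.0 + drift / 100.0) ** years
                profiles = [
                    p.scale_uptake(factor) if p.region_label in ("WBS", "WMBS") else p
                    for p in profiles
                ]
            dose = float(np.clip(rng.normal(370.0, 30.0), 300.0, 440.0))
            input_fn, _ = make_input_function(
                amplitude=amp * (dose / 370.0) * (75.0 / weight)
            )
            noise_seed = int(rng.integers(2**31))
            session, truth = generate_scan(
                profiles,
                input_fn,
                default_schedule(),
                noise_level=scenario.noise_level,
                seed=noise_seed,
                subject_id=subject,
                scan_id=f"{subject}_{role}",
                scan_role=role,
                injected_dose_MBq=dose,
                weight_kg=weight,
                visual_status=status,
                followup_years=years if role == "followup" else None,
            )
            session.input_function = None  # no arterial sampling in this design
            sessions.append(session)
            truths.append(truth)
    return sessions, pd.concat(truths, ignore_index=True)
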