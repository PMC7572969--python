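"""End-to-end orchestration: quantify scans, then compare reference regions.

``run_quantify`` turns ScanSessions into a ParameterTable (one row per scan x
region x method x reference region, plus a volume-weighted composite row per
method x reference); ``run_compare`` feeds the table(s) into the statistics
layer.  Plasma-input fits are skipped per scan, with a logged reason, when no
arterial data are attached -- mirroring cohorts with only partial arterial
availability.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field as dataclass_field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import comparison_stats, kinetic_models, semiquant
from .comparison_stats import ComparisonReport, ReportConfig
from .synthetic_cohort import DEFAULT_VOLUMES
from .tac_core import (
    COMPOSITE_REGION,
    REFERENCE_REGIONS,
    ParameterTable,
    ScanSession,
    composite_global,
)

log = logging.getLogger("pibquant")

RATIO_METHODS = ("DVR_PI", "DVR_RLOGAN", "DVR_SRTM", "SUVR_40_60", "SUVR_60_90")


@dataclass
class PipelineConfig:
    """Everything the pipeline needs to run reproducibly from one object."""

    methods: tuple[str, ...] = RATIO_METHODS
    reference_regions: tuple[str, ...] = REFERENCE_REGIONS
    gold_method: str = "DVR_PI"
    gold_reference: str = "GMCB"
    t_star: float = kinetic_models.DEFAULT_T_STAR
    weights: str = "duration"  # duration | uniform
    n_starts_2t4k: int = 5
    n_starts_srtm: int = 3
    bounds_2t4k: dict = dataclass_field(default_factory=dict)
    # per-reference-region SRTM bound overrides
    srtm_bounds: dict = dataclass_field(
        default_factory=lambda: dict(kinetic_models.SRTM_BOUNDS_PER_REFERENCE)
    )
    windows: tuple[semiquant.SUVWindow, ...] = semiquant.DEFAULT_WINDOWS
    include_reference_suv: bool = True
    stability_family: int = 5
    discrimination_family: int = 20
    target_years: float = comparison_stats.DEFAULT_TARGET_YEARS
    seed: int = 0

    def report_config(self) -> ReportConfig:
        ratio = tuple(m for m in self.methods if m != self.gold_method)
        return ReportConfig(
            gold_method=self.gold_method,
            gold_reference=self.gold_reference,
            reference_regions=self.reference_regions,
            ratio_methods=ratio,
            target_years=self.target_years,
            stability_family=self.stability_family,
            discrimination_family=self.discrimination_family,
        )

    @staticmethod
    def from_yaml(path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        if "methods" in d:
            d["methods"] = tuple(d["methods"])
        if "reference_regions" in d:
            d["reference_regions"] = tuple(d["reference_regions"])
        if "windows" in d:
            d["windows"] = tuple(
                semiquant.SUVWindow(w["t0"], w["t1"], w.get("label", "")) for w in d["windows"]
            )
        return PipelineConfig(**d)


def _fit_seed(base: int, *parts: str) -> int:
    """Stable per-fit seed fanned out from the single config seed."""
    return (base + zlib.crc32(":".join(parts).encode())) & 0x7FFFFFFF


def _volumes(session: ScanSession) -> dict[str, float]:
    vols = {}
    for region, tac in session.tacs.items():
        vols[region] = tac.volume_ml if tac.volume_ml is not None else DEFAULT_VOLUMES.get(region, 1.0)
    return vols


def _window_method(window: semiquant.SUVWindow, prefix: str) -> str:
    return f"{prefix}_{window.label.replace('-', '_')}"


def quantify_session(session: ScanSession, config: PipelineConfig | None = None) -> ParameterTable:
    """Quantify one scan with every requested method x reference region."""
    cfg = config or PipelineConfig()
    targets = session.target_regions()
    refs = [r for r in cfg.reference_regions if r in session.tacs]
    if not refs:
        raise ValueError(f"scan {session.scan_id}: no reference-region TAC present")
    volumes = _volumes(session)
    rows: list[dict] = []

    def add(region: str, method: str, ref: str, value: float) -> None:
        rows.append(
            {
                "subject_id": session.subject_id,
                "scan_id": session.scan_id,
                "region": region,
                "method": method,
                "reference_region": ref,
                "value": value,
                "excluded": False,
            }
        )

    def add_with_composite(method: str, ref: str, values: dict[str, float]) -> None:
        for region, value in values.items():
            add(region, method, ref, value)
        add(COMPOSITE_REGION, method, ref, composite_global(values, volumes, targets))

    # plasma-input model: fit each region once, then form ratios per reference
    if "DVR_PI" in cfg.methods:
        if session.input_function is None:
            log.warning(
                "scan %s: DVR_PI requested but no arterial input attached; skipping",
                session.scan_id,
            )
        else:
            vt: dict[str, float] = {}
            for region in list(targets) + refs:
                seed = _fit_seed(cfg.seed, session.scan_id, region, "2t4k")
                params, diag = kinetic_models.fit_2t4k_vb(
                    session.tacs[region],
                    session.input_function,
                    weights=cfg.weights,
                    bounds=cfg.bounds_2t4k or None,
                    n_starts=cfg.n_starts_2t4k,
                    seed=seed,
                )
                if any(diag.parameter_at_bound.values()):
                    at = [k for k, v in diag.parameter_at_bound.items() if v]
                    log.debug("scan %s region %s: parameters at bound: %s", session.scan_id, region, at)
                vt[region] = params.VT
            for ref in refs:
                values = {t: kinetic_models.dvr_from_vt(vt[t], vt[ref]) for t in targets}
                add_with_composite("DVR_PI", ref, values)

    for ref in refs:
        ref_tac = session.tacs[ref]
        if "DVR_RLOGAN" in cfg.methods:
            values = {
                t: kinetic_models.rlogan_dvr(session.tacs[t], ref_tac, t_star=cfg.t_star).DVR
                for t in targets
            }
            add_with_composite("DVR_RLOGAN", ref, values)
        if "DVR_SRTM" in cfg.methods:
            values = {}
            for t in targets:
                seed = _fit_seed(cfg.seed, session.scan_id, t, ref, "srtm")
                params, _ = kinetic_models.fit_srtm(
                    session.tacs[t],
                    ref_tac,
                    weights=cfg.weights,
                    bounds=cfg.srtm_bounds.get(ref) or None,
                    n_starts=cfg.n_starts_srtm,
                    seed=seed,
                )
                values[t] = params.DVR
            add_with_composite("DVR_SRTM", ref, values)
        for window in cfg.windows:
            method = _window_method(window, "SUVR")
            if method in cfg.methods:
                values = {
                    t: semiquant.suvr_window(session.tacs[t], ref_tac, window) for t in targets
                }
                add_with_composite(method, ref, values)

    if cfg.include_reference_suv:
        if session.injected_dose_MBq is None or session.weight_kg is None:
            log.info("scan %s: dose/weight unavailable; reference SUVs skipped", session.scan_id)
        else:
            for window in cfg.windows:
                for ref in refs:
                    suv = semiquant.suv_window(
                        session.tacs[ref], session.injected_dose_MBq, session.weight_kg, window
                    )
                    add(ref, _window_method(window, "SUV"), "none", suv)

    return ParameterTable.from_rows(rows)


def run_quantify(
    sessions: Sequence[ScanSession], config: PipelineConfig | None = None
) -> ParameterTable:
    """Quantify a list of sessions into one ParameterTable."""
    tables = [quantify_session(s, config) for s in sessions]
    return ParameterTable.concat(tables)


def sessions_metadata(sessions: Sequence[ScanSession]) -> pd.DataFrame:
    """Per-scan metadata table the statistics layer consumes."""
    return pd.DataFrame(
        [
            {
                "subject_id": s.subject_id,
                "scan_id": s.scan_id,
                "scan_role": s.scan_role,
                "visual_status": s.visual_status,
                "diagnosis": s.diagnosis,
                "followup_years": s.followup_years,
            }
            for s in sessions
        ]
    )


def run_compare(
    parameter_tables: "ParameterTable | list[ParameterTable]",
    metadata: pd.DataFrame,
    config: PipelineConfig | None = None,
    out_dir: "str | Path | None" = None,
) -> ComparisonReport:
    """Run the comparison battery; optionally write report JSON + CSVs."""
    cfg = config or PipelineConfig()
    _validate_roles(metadata)
    report = comparison_stats.build_comparison_report(
        parameter_tables, metadata, cfg.report_config()
    )
    for _, row in report.exclusions.iterrows():
        log.info(
            "excluded %s/%s %s %s/%s value %.4g (group median %.4g, MAD %.4g)",
            row["subject_id"], row["scan_id"], row["region"], row["method"],
            row["reference_region"], row["value"], row["group_median"], row["group_mad"],
        )
    if out_dir is not None:
        report.write(out_dir)
    return report


def _validate_roles(metadata: pd.DataFrame) -> None:
    valid = {"test", "retest", "baseline", "followup"}
    bad = metadata[~metadata["scan_role"].isin(valid)]
    if not bad.empty:
        raise ValueError(f"invalid scan roles:\n{bad[['subject_id', 'scan_id', 'scan_role']]}")


def write_metadata(metadata: pd.DataFrame, path: str | Path) -> None:
    records = metadata.where(pd.notna(metadata), None).to_dict(orient="records")
    Path(path).write_text(yaml.safe_dump(records, sort_keys=True))


def read_metadata(path: str | Path) -> pd.DataFrame:
    records = yaml.safe_load(Path(path).read_text())
    return pd.DataFrame(records)
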