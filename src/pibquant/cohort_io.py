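"""Directory layout for cohorts of scans.

One directory per cohort, three delimited-text files per scan plus a shared
truth sidecar for synthetic data:

    <scan_id>_tacs.csv   frame_start_min, frame_duration_min, <region>...
    <scan_id>_meta.yaml  subject/scan ids, role, dose, weight, status, volumes
    <scan_id>_blood.csv  time_min, whole_blood_kBq_ml and either
                         plasma_parent_kBq_ml (precomputed parent curve) or
                         plasma_to_wb_ratio + parent_fraction columns
    truth.csv            generating parameters, true V_T and DVR per region
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd

from .blood_input import CorrectionModel, InputFunction, derive_plasma_input
from .tac_core import ScanSession, read_session, write_session


def write_cohort(
    sessions: Sequence[ScanSession],
    out_dir: str | Path,
    truth: pd.DataFrame | None = None,
) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for session in sessions:
        stem = out / session.scan_id
        write_session(session, f"{stem}_tacs.csv", f"{stem}_meta.yaml")
        fn = session.input_function
        if fn is not None:
            pd.DataFrame(
                {
                    "time_min": fn.times,
                    "whole_blood_kBq_ml": fn.whole_blood,
                    "plasma_parent_kBq_ml": fn.plasma_parent,
                }
            ).to_csv(f"{stem}_blood.csv", index=False, float_format="%.10g")
    if truth is not None:
        truth.to_csv(out / "truth.csv", index=False, float_format="%.10g")


def _read_blood(path: Path) -> InputFunction:
    df = pd.read_csv(path)
    times = df["time_min"].to_numpy(dtype=float)
    wb = df["whole_blood_kBq_ml"].to_numpy(dtype=float)
    if "plasma_parent_kBq_ml" in df.columns:
        return InputFunction(times, df["plasma_parent_kBq_ml"].to_numpy(dtype=float), wb)
    if {"plasma_to_wb_ratio", "parent_fraction"} <= set(df.columns):
        corrections = CorrectionModel.from_tables(
            times, df["plasma_to_wb_ratio"], df["parent_fraction"]
        )
        return derive_plasma_input(
            pd.DataFrame({"t": times, "wb": wb}).to_numpy(), corrections, times
        )
    raise ValueError(
        f"{path}: need plasma_parent_kBq_ml or plasma_to_wb_ratio + parent_fraction columns"
    )


def read_cohort(in_dir: str | Path) -> tuple[list[ScanSession], pd.DataFrame | None]:
    """Read every scan in a cohort directory; returns (sessions, truth-or-None)."""
    src = Path(in_dir)
    sessions = []
    for meta_path in sorted(src.glob("*_meta.yaml")):
        stem = meta_path.name[: -len("_meta.yaml")]
        tac_path = src / f"{stem}_tacs.csv"
        if not tac_path.exists():
            raise FileNotFoundError(f"missing TAC table for {meta_path}")
        session = read_session(tac_path, meta_path)
        blood_path = src / f"{stem}_blood.csv"
        if blood_path.exists():
            session.input_function = _read_blood(blood_path)
        sessions.append(session)
    truth_path = src / "truth.csv"
    truth = pd.read_csv(truth_path) if truth_path.exists() else None
    return sessions, truth
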