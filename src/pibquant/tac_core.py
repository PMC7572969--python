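"""Core domain objects for regional dynamic-PET data.

Everything downstream of image processing works on regional time-activity
curves (TACs): decay-corrected activity concentration (kBq/mL) sampled over a
frame schedule, in minutes.  Frame values are treated as instantaneous samples
at frame mid-times for integration and model fitting, and the underlying curve
is taken to be 0 at t = 0 (tracer not yet arrived) and linearly interpolated
between samples.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

#: The five candidate reference regions compared throughout the package:
#: cerebellar grey matter, whole cerebellum, white-matter brainstem/pons,
#: whole brainstem, and eroded subcortical white matter.
REFERENCE_REGIONS = ("GMCB", "WCB", "WMBS", "WBS", "WMES")

#: Default cortical target regions (Hammers-atlas style grey-matter labels).
DEFAULT_TARGET_REGIONS = (
    "medial_anterior_temporal",
    "lateral_anterior_temporal",
    "posterior_temporal",
    "superior_temporal_gyrus",
    "middle_temporal_gyrus",
    "inferior_temporal_gyrus",
    "fusiform_gyrus",
    "parahippocampal_ambient_gyrus",
    "anterior_cingulate",
    "posterior_cingulate",
    "middle_frontal_gyrus",
    "orbitofrontal_gyrus",
    "gyrus_rectus",
    "inferior_frontal_gyrus",
    "superior_frontal_gyrus",
    "precentral_gyrus",
    "postcentral_gyrus",
    "superior_parietal_gyrus",
    "inferolateral_parietal",
)

COMPOSITE_REGION = "composite"

_OVERLAP_TOL = 1e-9


class TacFormatError(ValueError):
    """A delimited-text table does not have the expected layout."""


class TacValidationError(ValueError):
    """A domain invariant (frame ordering, positivity, ...) is violated."""


@dataclass(frozen=True)
class FrameSchedule:
    """Frame timing of a dynamic scan: per-frame start times and durations (min)."""

    start_times: np.ndarray
    durations: np.ndarray

    def __post_init__(self) -> None:
        starts = np.asarray(self.start_times, dtype=float)
        durs = np.asarray(self.durations, dtype=float)
        object.__setattr__(self, "start_times", starts)
        object.__setattr__(self, "durations", durs)
        if starts.ndim != 1 or durs.ndim != 1 or starts.size != durs.size:
            raise TacValidationError("start_times and durations must be 1-D and equal length")
        if starts.size == 0:
            raise TacValidationError("schedule must contain at least one frame")
        if not np.all(np.isfinite(starts)) or not np.all(np.isfinite(durs)):
            raise TacValidationError("schedule times must be finite")
        if np.any(durs <= 0):
            raise TacValidationError("frame durations must be positive")
        if np.any(np.diff(starts) <= 0):
            raise TacValidationError("frame start times must be strictly increasing")
        ends = starts + durs
        if np.any(ends[:-1] > starts[1:] + _OVERLAP_TOL):
            raise TacValidationError("frames must not overlap")

    @property
    def n_frames(self) -> int:
        return int(self.start_times.size)

    @property
    def end_time(self) -> float:
        """Scan end (min): end of the last frame."""
        return float(self.start_times[-1] + self.durations[-1])

    def mid_times(self) -> np.ndarray:
        return frame_midtimes(self)


@dataclass(frozen=True)
class TimeActivityCurve:
    """Frame-sampled activity concentration (kBq/mL) of one region."""

    schedule: FrameSchedule
    values: np.ndarray
    region_label: str = ""
    volume_ml: float | None = None

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if vals.ndim != 1 or vals.size != self.schedule.n_frames:
            raise TacValidationError(
                f"TAC for {self.region_label!r}: expected {self.schedule.n_frames} "
                f"values, got {vals.size}"
            )
        if not np.all(np.isfinite(vals)):
            raise TacValidationError(f"TAC for {self.region_label!r} contains non-finite values")
        if self.volume_ml is not None and not self.volume_ml > 0:
            raise TacValidationError("volume_ml must be positive when given")

    def with_values(self, values: np.ndarray) -> "TimeActivityCurve":
        return replace(self, values=np.asarray(values, dtype=float))

    def sample_points(self) -> tuple[np.ndarray, np.ndarray]:
        """Knots of the piecewise-linear curve: (0, 0) then (mid-time, value)."""
        mids = self.schedule.mid_times()
        t = np.concatenate(([0.0], mids))
        v = np.concatenate(([0.0], self.values))
        return t, v

    def interp(self, t: np.ndarray) -> np.ndarray:
        """Curve value at arbitrary times; held constant beyond the last mid-time."""
        knots_t, knots_v = self.sample_points()
        return np.interp(np.asarray(t, dtype=float), knots_t, knots_v)


@dataclass
class ScanSession:
    """One dynamic scan: all regional TACs plus acquisition/subject metadata."""

    subject_id: str
    scan_id: str
    scan_role: str  # test | retest | baseline | followup
    tacs: dict[str, TimeActivityCurve]
    injected_dose_MBq: float | None = None
    weight_kg: float | None = None
    input_function: object | None = None  # blood_input.InputFunction
    visual_status: str | None = None  # positive | negative
    diagnosis: str | None = None  # CU | MCI | AD
    followup_years: float | None = None

    _ROLES = ("test", "retest", "baseline", "followup")

    def __post_init__(self) -> None:
        if self.scan_role not in self._ROLES:
            raise TacValidationError(f"scan_role must be one of {self._ROLES}")
        if not self.tacs:
            raise TacValidationError("session must contain at least one TAC")
        ref = next(iter(self.tacs.values())).schedule
        for tac in self.tacs.values():
            if tac.schedule is not ref and not (
                np.array_equal(tac.schedule.start_times, ref.start_times)
                and np.array_equal(tac.schedule.durations, ref.durations)
            ):
                raise TacValidationError("all TACs in a session must share one frame schedule")
        if self.injected_dose_MBq is not None and not self.injected_dose_MBq > 0:
            raise TacValidationError("injected_dose_MBq must be positive")
        if self.weight_kg is not None and not self.weight_kg > 0:
            raise TacValidationError("weight_kg must be positive")
        if self.visual_status not in (None, "positive", "negative"):
            raise TacValidationError("visual_status must be 'positive' or 'negative'")
        if self.followup_years is not None and not self.followup_years > 0:
            raise TacValidationError("followup_years must be positive")

    @property
    def schedule(self) -> FrameSchedule:
        return next(iter(self.tacs.values())).schedule

    @property
    def regions(self) -> list[str]:
        return list(self.tacs)

    def reference_regions(self) -> list[str]:
        return [r for r in self.tacs if r in REFERENCE_REGIONS]

    def target_regions(self) -> list[str]:
        return [r for r in self.tacs if r not in REFERENCE_REGIONS]


PARAMETER_TABLE_COLUMNS = (
    "subject_id",
    "scan_id",
    "region",
    "method",
    "reference_region",
    "value",
    "excluded",
)

#: Outcome methods carried by a ParameterTable.  DVR_* and SUVR_* are ratios
#: against a reference region; SUV_* rows hold absolute reference-region SUVs
#: (reference_region = "none") for the longitudinal stability analysis.
METHODS = (
    "DVR_PI",
    "DVR_RLOGAN",
    "DVR_SRTM",
    "SUVR_40_60",
    "SUVR_60_90",
    "SUV_40_60",
    "SUV_60_90",
)


@dataclass
class ParameterTable:
    """Region x method x reference-region outcome grid, one row per estimate.

    This is the pipeline's interchange object between quantification and the
    statistics layer; it round-trips losslessly through CSV.
    """

    data: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=list(PARAMETER_TABLE_COLUMNS)))

    def __post_init__(self) -> None:
        df = self.data.copy()
        missing = set(PARAMETER_TABLE_COLUMNS) - set(df.columns)
        if missing:
            raise TacFormatError(f"parameter table missing columns: {sorted(missing)}")
        df = df[list(PARAMETER_TABLE_COLUMNS)]
        df["value"] = df["value"].astype(float)
        df["excluded"] = df["excluded"].astype(bool)
        key = ["subject_id", "scan_id", "region", "method", "reference_region"]
        if df.duplicated(subset=key).any():
            dup = df[df.duplicated(subset=key, keep=False)].head()
            raise TacValidationError(f"duplicate parameter rows, e.g.\n{dup}")
        bad = ~np.isfinite(df["value"].to_numpy()) & ~df["excluded"].to_numpy()
        if bad.any():
            raise TacValidationError("non-finite values allowed only on excluded rows")
        self.data = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    def included(self) -> pd.DataFrame:
        return self.data[~self.data["excluded"]]

    @staticmethod
    def from_rows(rows: list[dict]) -> "ParameterTable":
        return ParameterTable(pd.DataFrame(rows, columns=list(PARAMETER_TABLE_COLUMNS)))

    @staticmethod
    def concat(tables: list["ParameterTable"]) -> "ParameterTable":
        return ParameterTable(pd.concat([t.data for t in tables], ignore_index=True))


# ---------------------------------------------------------------------------
# operations


def frame_midtimes(schedule: FrameSchedule) -> np.ndarray:
    """Frame mid-times (min): start + duration / 2."""
    return schedule.start_times + schedule.durations / 2.0


def integrate_tac(tac: TimeActivityCurve, t0: float, t1: float) -> float:
    """Trapezoidal integral (kBq*min/mL) of the mid-time-sampled curve over [t0, t1].

    The curve is 0 at t = 0, linear between mid-time samples, and held at the
    last sample value out to the scan end.
    """
    if not t0 < t1:
        raise ValueError(f"need t0 < t1, got [{t0}, {t1}]")
    end = tac.schedule.end_time
    if t0 < -_OVERLAP_TOL or t1 > end + _OVERLAP_TOL:
        raise ValueError(f"window [{t0}, {t1}] outside scan range [0, {end}]")
    knots_t, knots_v = tac.sample_points()
    inner = knots_t[(knots_t > t0) & (knots_t < t1)]
    grid = np.concatenate(([t0], inner, [t1]))
    vals = np.interp(grid, knots_t, knots_v)
    return float(np.trapezoid(vals, grid))


def composite_global(
    values: Mapping[str, float],
    volumes: Mapping[str, float],
    target_regions: "list[str] | tuple[str, ...]",
) -> float:
    """Volume-weighted average of regional values across target regions only."""
    total_vol = 0.0
    acc = 0.0
    for region in target_regions:
        if region not in values:
            raise KeyError(f"no value for target region {region!r}")
        if region not in volumes:
            raise KeyError(f"no volume for target region {region!r}")
        vol = float(volumes[region])
        if vol <= 0:
            raise TacValidationError(f"volume for {region!r} must be positive")
        acc += float(values[region]) * vol
        total_vol += vol
    if total_vol <= 0:
        raise TacValidationError("total target volume is zero")
    return acc / total_vol


# ---------------------------------------------------------------------------
# delimited-text I/O

_TIME_COLS = ("frame_start_min", "frame_duration_min")


def _read_table(path: str | Path) -> pd.DataFrame:
    # comma/tab autodetection via the python engine's sniffer
    try:
        df = pd.read_csv(path, sep=None, engine="python", comment="#")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise TacFormatError(f"cannot parse TAC table {path}: {exc}") from exc
    return df


def read_tacs(path: str | Path, volumes: Mapping[str, float] | None = None) -> dict[str, TimeActivityCurve]:
    """Read a TAC table: columns frame_start_min, frame_duration_min, <region>..."""
    df = _read_table(path)
    for col in _TIME_COLS:
        if col not in df.columns:
            raise TacFormatError(f"TAC table {path} missing column {col!r}")
    region_cols = [c for c in df.columns if c not in _TIME_COLS]
    if not region_cols:
        raise TacFormatError(f"TAC table {path} has no region columns")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        raise TacFormatError(f"TAC table {path} contains non-numeric entries")
    schedule = FrameSchedule(
        numeric["frame_start_min"].to_numpy(), numeric["frame_duration_min"].to_numpy()
    )
    tacs = {}
    for region in region_cols:
        vol = None if volumes is None else volumes.get(region)
        tacs[region] = TimeActivityCurve(
            schedule, numeric[region].to_numpy(), region_label=region, volume_ml=vol
        )
    return tacs


def write_tacs(tacs: Mapping[str, TimeActivityCurve], path: str | Path) -> None:
    first = next(iter(tacs.values()))
    data = {
        "frame_start_min": first.schedule.start_times,
        "frame_duration_min": first.schedule.durations,
    }
    for region, tac in tacs.items():
        data[region] = tac.values
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.10g")


def _load_metadata(metadata: "str | Path | Mapping") -> dict:
    if isinstance(metadata, Mapping):
        return dict(metadata)
    path = Path(metadata)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def read_session(
    tac_table_path: str | Path,
    metadata_config: "str | Path | Mapping",
    volumes: Mapping[str, float] | None = None,
) -> ScanSession:
    """Assemble a validated ScanSession from a TAC table and a metadata config."""
    meta = _load_metadata(metadata_config)
    if volumes is None:
        volumes = meta.get("volumes_ml")
    tacs = read_tacs(tac_table_path, volumes=volumes)
    return ScanSession(
        subject_id=str(meta["subject_id"]),
        scan_id=str(meta["scan_id"]),
        scan_role=meta.get("scan_role", "test"),
        tacs=tacs,
        injected_dose_MBq=meta.get("injected_dose_MBq"),
        weight_kg=meta.get("weight_kg"),
        visual_status=meta.get("visual_status"),
        diagnosis=meta.get("diagnosis"),
        followup_years=meta.get("followup_years"),
    )


def write_session(session: ScanSession, tac_table_path: str | Path, metadata_path: str | Path) -> None:
    """Write a session back to the TAC-table + metadata-config file pair."""
    write_tacs(session.tacs, tac_table_path)
    meta = {
        "subject_id": session.subject_id,
        "scan_id": session.scan_id,
        "scan_role": session.scan_role,
        "injected_dose_MBq": session.injected_dose_MBq,
        "weight_kg": session.weight_kg,
        "visual_status": session.visual_status,
        "diagnosis": session.diagnosis,
        "followup_years": session.followup_years,
        "volumes_ml": {
            r: t.volume_ml for r, t in session.tacs.items() if t.volume_ml is not None
        } or None,
    }
    meta = {k: v for k, v in meta.items() if v is not None}
    Path(metadata_path).write_text(yaml.safe_dump(meta, sort_keys=True))


def write_parameter_table(table: ParameterTable, path: str | Path) -> None:
    table.data.to_csv(path, index=False, float_format="%.12g")


def read_parameter_table(path: str | Path) -> ParameterTable:
    df = pd.read_csv(path)
    return ParameterTable(df)
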