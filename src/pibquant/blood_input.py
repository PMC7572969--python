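"""Arterial input handling.

The plasma-input model needs two curves on a common fine time grid: the
metabolite-corrected plasma parent concentration C_p(t) (its driving input)
and the whole-blood concentration C_wb(t) (for the fractional blood-volume
term).  Continuous/manual blood sampling yields whole-blood activity plus two
time-dependent corrections: the plasma-to-whole-blood ratio and the fraction
of plasma activity that is unchanged parent tracer,

    C_p(t) = C_wb(t) * ratio(t) * parent_fraction(t).

Corrections are supplied as sampled tables and interpolated linearly; the
whole-blood curve is pinned to 0 at t = 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

#: Default fine-grid spacing (min) used for convolution and input resampling.
DEFAULT_GRID_STEP = 0.05


class BloodValidationError(ValueError):
    """A blood-curve or correction-model invariant is violated."""


def default_grid(end_time: float, step: float = DEFAULT_GRID_STEP) -> np.ndarray:
    """Uniform grid 0..end_time inclusive (min)."""
    n = int(round(end_time / step))
    return np.linspace(0.0, n * step, n + 1)


@dataclass(frozen=True)
class InputFunction:
    """Metabolite-corrected plasma and whole-blood curves on one fine grid."""

    times: np.ndarray
    plasma_parent: np.ndarray
    whole_blood: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        cp = np.asarray(self.plasma_parent, dtype=float)
        wb = np.asarray(self.whole_blood, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "plasma_parent", cp)
        object.__setattr__(self, "whole_blood", wb)
        if t.ndim != 1 or t.size < 2:
            raise BloodValidationError("times must be a 1-D grid with >= 2 points")
        if abs(t[0]) > 1e-12:
            raise BloodValidationError("input-function grid must start at 0")
        if np.any(np.diff(t) <= 0):
            raise BloodValidationError("times must be strictly increasing")
        if cp.shape != t.shape or wb.shape != t.shape:
            raise BloodValidationError("curves must match the time grid length")
        if np.any(cp < -1e-12) or np.any(wb < -1e-12):
            raise BloodValidationError("blood curves must be non-negative")

    @property
    def end_time(self) -> float:
        return float(self.times[-1])

    def plasma_at(self, t: np.ndarray) -> np.ndarray:
        return np.interp(t, self.times, self.plasma_parent)

    def whole_blood_at(self, t: np.ndarray) -> np.ndarray:
        return np.interp(t, self.times, self.whole_blood)


@dataclass(frozen=True)
class CorrectionModel:
    """Time-dependent plasma/whole-blood ratio and parent fraction.

    Both are callables of time (min); ``from_tables`` builds them by linear
    interpolation of sampled values.  parent_fraction(0) must be 1 (nothing is
    metabolised before the tracer arrives).
    """

    plasma_to_wholeblood: Callable[[np.ndarray], np.ndarray]
    parent_fraction: Callable[[np.ndarray], np.ndarray]

    @staticmethod
    def from_tables(
        times: Sequence[float],
        ratio: Sequence[float],
        parent_fraction: Sequence[float],
    ) -> "CorrectionModel":
        t = np.asarray(times, dtype=float)
        r = np.asarray(ratio, dtype=float)
        pf = np.asarray(parent_fraction, dtype=float)
        if np.any(r <= 0):
            raise BloodValidationError("plasma/whole-blood ratio must be positive")
        if np.any((pf < 0) | (pf > 1)):
            raise BloodValidationError("parent fraction must lie in [0, 1]")
        pf0 = np.interp(0.0, t, pf)
        if abs(pf0 - 1.0) > 1e-6:
            raise BloodValidationError("parent_fraction(0) must be 1")
        return CorrectionModel(
            plasma_to_wholeblood=lambda x: np.interp(x, t, r),
            parent_fraction=lambda x: np.interp(x, t, pf),
        )

    @staticmethod
    def identity() -> "CorrectionModel":
        return CorrectionModel(
            plasma_to_wholeblood=lambda t: np.ones_like(np.asarray(t, dtype=float)),
            parent_fraction=lambda t: np.ones_like(np.asarray(t, dtype=float)),
        )


def resample_curve(times: np.ndarray, values: np.ndarray, new_grid: np.ndarray) -> np.ndarray:
    """Linear resampling onto new_grid; the curve is 0-extended to t = 0.

    Extrapolation beyond the last sample is refused: tail behaviour should be
    modelled explicitly, not guessed.
    """
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    g = np.asarray(new_grid, dtype=float)
    if t.ndim != 1 or t.size < 2 or np.any(np.diff(t) <= 0):
        raise BloodValidationError("sample times must be 1-D, >= 2 points, strictly increasing")
    if t[0] > 0:
        t = np.concatenate(([0.0], t))
        v = np.concatenate(([0.0], v))
    if g.min() < t[0] - 1e-12 or g.max() > t[-1] + 1e-12:
        raise ValueError(
            f"grid [{g.min()}, {g.max()}] outside sample range [{t[0]}, {t[-1]}]"
        )
    return np.interp(g, t, v)


def derive_plasma_input(
    whole_blood_samples: Sequence[tuple[float, float]] | np.ndarray,
    corrections: CorrectionModel,
    grid: np.ndarray,
) -> InputFunction:
    """Build the metabolite-corrected plasma input from whole-blood samples.

    plasma_parent(t) = whole_blood(t) * ratio(t) * parent_fraction(t), with the
    whole-blood curve linearly interpolated and pinned to 0 at t = 0.
    """
    samples = np.asarray(whole_blood_samples, dtype=float)
    if samples.ndim != 2 or samples.shape[1] != 2 or samples.shape[0] < 2:
        raise BloodValidationError("need >= 2 (time, activity) whole-blood samples")
    grid = np.asarray(grid, dtype=float)
    wb = resample_curve(samples[:, 0], samples[:, 1], grid)
    ratio = np.asarray(corrections.plasma_to_wholeblood(grid), dtype=float)
    pf = np.asarray(corrections.parent_fraction(grid), dtype=float)
    if np.any(ratio <= 0):
        raise BloodValidationError("plasma/whole-blood ratio must be positive on the grid")
    if np.any((pf < -1e-12) | (pf > 1 + 1e-12)):
        raise BloodValidationError("parent fraction must lie in [0, 1] on the grid")
    cp = wb * ratio * np.clip(pf, 0.0, 1.0)
    return InputFunction(times=grid, plasma_parent=cp, whole_blood=wb)


# ---------------------------------------------------------------------------
# delimited-text I/O


def read_blood_table(path: str | Path) -> tuple[np.ndarray, CorrectionModel | None]:
    """Read `time_min, whole_blood_kBq_ml[, plasma_to_wb_ratio, parent_fraction]`.

    Returns (samples, corrections); corrections is None when the optional
    columns are absent.
    """
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    for col in ("time_min", "whole_blood_kBq_ml"):
        if col not in df.columns:
            raise BloodValidationError(f"blood table {path} missing column {col!r}")
    samples = df[["time_min", "whole_blood_kBq_ml"]].to_numpy(dtype=float)
    corrections = None
    if {"plasma_to_wb_ratio", "parent_fraction"} <= set(df.columns):
        corrections = CorrectionModel.from_tables(
            df["time_min"].to_numpy(dtype=float),
            df["plasma_to_wb_ratio"].to_numpy(dtype=float),
            df["parent_fraction"].to_numpy(dtype=float),
        )
    return samples, corrections


def write_blood_table(
    path: str | Path,
    times: np.ndarray,
    whole_blood: np.ndarray,
    ratio: np.ndarray | None = None,
    parent_fraction: np.ndarray | None = None,
) -> None:
    data = {"time_min": times, "whole_blood_kBq_ml": whole_blood}
    if ratio is not None:
        data["plasma_to_wb_ratio"] = ratio
    if parent_fraction is not None:
        data["parent_fraction"] = parent_fraction
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.10g")
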