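"""Semi-quantitative amyloid measures: SUV and SUVr over acquisition windows.

SUV normalises activity concentration by injected dose per body weight, so a
uniformly distributed tracer gives SUV = 1 g/mL everywhere.  SUVr is the
target/reference SUV ratio over a window; dose and weight cancel, so it is
computable without them.  The two canonical windows are 40-60 and 60-90 min
post injection.  Window means are time-integrals divided by window length
(robust to unequal frame durations), not unweighted frame means.
"""

from __future__ import annotations

from dataclasses import dataclass

from .tac_core import TimeActivityCurve, integrate_tac


class SUVUnavailableError(ValueError):
    """Dose or weight missing, so an absolute SUV cannot be computed."""


@dataclass(frozen=True)
class SUVWindow:
    t0: float  # min
    t1: float  # min
    label: str = ""

    def __post_init__(self) -> None:
        if not 0 <= self.t0 < self.t1:
            raise ValueError("need 0 <= t0 < t1")
        if not self.label:
            object.__setattr__(self, "label", f"{self.t0:g}-{self.t1:g}")


WINDOW_40_60 = SUVWindow(40.0, 60.0, "40-60")
WINDOW_60_90 = SUVWindow(60.0, 90.0, "60-90")
DEFAULT_WINDOWS = (WINDOW_40_60, WINDOW_60_90)


def window_mean(tac: TimeActivityCurve, window: SUVWindow) -> float:
    """Time-averaged activity (kBq/mL) over the window."""
    return integrate_tac(tac, window.t0, window.t1) / (window.t1 - window.t0)


def suv_window(
    tac: TimeActivityCurve,
    dose_MBq: float | None,
    weight_kg: float | None,
    window: SUVWindow,
) -> float:
    """Standardised uptake value (g/mL) over the window.

    mean activity (kBq/mL) / (dose (kBq) / weight (g)); with dose in MBq and
    weight in kg the normaliser is dose_MBq/weight_kg in kBq/g.
    """
    if dose_MBq is None or weight_kg is None:
        raise SUVUnavailableError("injected dose and body weight are required for SUV")
    if dose_MBq <= 0 or weight_kg <= 0:
        raise ValueError("dose and weight must be positive")
    return window_mean(tac, window) * weight_kg / dose_MBq


def suvr_window(
    target: TimeActivityCurve,
    reference: TimeActivityCurve,
    window: SUVWindow,
) -> float:
    """SUV ratio: target window mean over reference window mean."""
    ref_mean = window_mean(reference, window)
    if ref_mean <= 0:
        raise ValueError("reference window mean must be positive")
    return window_mean(target, window) / ref_mean
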