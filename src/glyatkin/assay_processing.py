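"""Initial-rate extraction from DTNB plate-reader time courses.

The GLYAT assay couples glycine-dependent CoA release to Ellman's reagent
(DTNB): each free CoA thiol liberates one TNB anion absorbing at 412 nm.
A well's A412-vs-time trace is therefore proportional to product formed,
and the initial rate is the least-squares slope over the linear range of
the time course, converted with Beer-Lambert and expressed per mg enzyme
(umol min^-1 mg^-1).

The linear range is found with a deterministic prefix-window rule: starting
from the first point, the window grows as long as it stays both straight
(R^2 above a threshold) and fast (mean slope retaining a fraction of the
early slope), which discards the decelerating tail caused by benzoyl-CoA
depletion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ExtractionError, ValidationError

__all__ = [
    "AssayConstants",
    "TimeCourse",
    "RATE_TABLE_COLUMNS",
    "absorbance_to_product",
    "detect_linear_range",
    "extract_initial_rate",
    "extract_rate_table",
]

#: Column schema of an initial-rate table (one row per well/replicate).
RATE_TABLE_COLUMNS = (
    "gly_mM", "benz_uM", "replicate", "rate",
    "n_points_used", "r_squared", "window_start_s", "window_end_s",
)


@dataclass(frozen=True)
class AssayConstants:
    """Optical constants of the DTNB/TNB detection system.

    epsilon_tnb is the molar extinction coefficient of the released
    thiophenolate at 412 nm (M^-1 cm^-1); path_length_cm the vertical light
    path of the filled well (200 uL in a standard 96-well plate is about a
    0.56 cm column); stoichiometry the mol TNB released per mol CoA (1:1,
    one thiol per CoA).
    """

    epsilon_tnb: float = 14_150.0
    path_length_cm: float = 0.56
    stoichiometry: float = 1.0

    def __post_init__(self) -> None:
        for name in ("epsilon_tnb", "path_length_cm", "stoichiometry"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValidationError(f"{name} must be positive, got {v!r}")


@dataclass
class TimeCourse:
    """One well's A412 trace with its assay context."""

    well_id: str
    replicate: int
    times: np.ndarray        # s, strictly increasing
    a412: np.ndarray         # absorbance units
    gly_mM: float
    benz_uM: float
    enzyme_mass_ug: float
    volume_uL: float
    blank_a412: float | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.a412 = np.asarray(self.a412, dtype=float)
        if self.times.ndim != 1 or self.times.size < 5:
            raise ValidationError(
                f"well {self.well_id}: need >= 5 time points, "
                f"got {self.times.size}"
            )
        if self.a412.shape != self.times.shape:
            raise ValidationError(
                f"well {self.well_id}: times and a412 lengths differ"
            )
        if not np.all(np.diff(self.times) > 0):
            raise ValidationError(
                f"well {self.well_id}: times must be strictly increasing"
            )
        if self.gly_mM < 0 or self.benz_uM < 0:
            raise ValidationError(
                f"well {self.well_id}: concentrations must be >= 0"
            )
        if self.enzyme_mass_ug <= 0 or self.volume_uL <= 0:
            raise ValidationError(
                f"well {self.well_id}: enzyme mass and volume must be > 0"
            )
        if int(self.replicate) < 1:
            raise ValidationError(f"well {self.well_id}: replicate must be >= 1")

    @property
    def n_points(self) -> int:
        return self.times.size


def absorbance_to_product(a412, constants: AssayConstants, volume_uL: float):
    """Blank-corrected absorbance -> product amount (umol CoA released).

    Beer-Lambert: concentration (M) = A / (epsilon * l); the amount is
    concentration * well volume, divided by the TNB:CoA stoichiometry.
    Small negative inputs (down to -0.01 AU, i.e. read noise around the
    blank) are clamped to zero with a data-quality warning beyond that.
    """
    if volume_uL <= 0:
        raise ValidationError("volume_uL must be > 0")
    a = np.asarray(a412, dtype=float)
    if np.any(a < -0.01):
        warnings.warn(
            "blank-corrected absorbance below -0.01 AU; clamping to 0",
            stacklevel=2,
        )
    a = np.clip(a, 0.0, None)
    conc_M = a / (constants.epsilon_tnb * constants.path_length_cm)
    amount_umol = conc_M * (volume_uL * 1e-6) * 1e6 / constants.stoichiometry
    return amount_umol if amount_umol.ndim else float(amount_umol)


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Least-squares slope, intercept and R^2; R^2 = 1 for a constant fit."""
    xm, ym = x.mean(), y.mean()
    sxx = float(np.sum((x - xm) ** 2))
    sxy = float(np.sum((x - xm) * (y - ym)))
    syy = float(np.sum((y - ym) ** 2))
    slope = sxy / sxx
    intercept = ym - slope * xm
    if syy <= 1e-30:
        return slope, intercept, 1.0
    r2 = (sxy * sxy) / (sxx * syy)
    return slope, intercept, float(r2)


def detect_linear_range(tc: TimeCourse, min_points: int = 5,
                        r2_min: float = 0.995,
                        slope_retention: float = 0.90) -> tuple[int, int]:
    """Return the half-open index window [start, stop) of the linear range.

    The window always starts at the first point and is the longest prefix
    whose least-squares R^2 is at least ``r2_min`` and whose slope retains
    at least ``slope_retention`` of the slope over the first ``min_points``
    points.  A flat (zero-slope) trace passes trivially.
    """
    if min_points < 3:
        raise ValidationError("min_points must be >= 3")
    n = tc.n_points
    if n < min_points:
        raise ExtractionError(
            f"well {tc.well_id}: only {n} points, need {min_points}"
        )
    t, y = tc.times, tc.a412
    ref_slope, _, _ = _ols(t[:min_points], y[:min_points])
    best_stop = None
    for stop in range(min_points, n + 1):
        slope, _, r2 = _ols(t[:stop], y[:stop])
        if r2 >= r2_min and slope >= slope_retention * ref_slope:
            best_stop = stop
    if best_stop is None:
        raise ExtractionError(
            f"well {tc.well_id}: no prefix window of >= {min_points} points "
            f"meets R^2 >= {r2_min} and slope retention >= {slope_retention}"
        )
    return 0, best_stop


def extract_initial_rate(tc: TimeCourse,
                         constants: AssayConstants | None = None,
                         min_points: int = 5, r2_min: float = 0.995,
                         slope_retention: float = 0.90) -> dict:
    """One well -> one initial-rate table row (specific activity).

    The per-well blank is subtracted when provided; otherwise the fitted
    intercept absorbs any baseline, so the slope - and hence the rate - is
    unbiased either way.  The A412 slope over the detected window is
    converted to umol product per minute and divided by the enzyme mass.
    """
    constants = constants or AssayConstants()
    start, stop = detect_linear_range(tc, min_points, r2_min, slope_retention)
    y = tc.a412 - (tc.blank_a412 or 0.0)
    slope_a412_per_s, _, r2 = _ols(tc.times[start:stop], y[start:stop])
    # A412 -> umol product is linear, so the slope converts directly:
    # umol = A * V_uL / (epsilon * l * stoichiometry)
    slope_umol_per_s = slope_a412_per_s * tc.volume_uL / (
        constants.epsilon_tnb * constants.path_length_cm
        * constants.stoichiometry)
    mass_mg = tc.enzyme_mass_ug / 1000.0
    rate = max(slope_umol_per_s * 60.0 / mass_mg, 0.0)
    return {
        "gly_mM": tc.gly_mM,
        "benz_uM": tc.benz_uM,
        "replicate": int(tc.replicate),
        "rate": rate,
        "n_points_used": stop - start,
        "r_squared": r2,
        "window_start_s": float(tc.times[start]),
        "window_end_s": float(tc.times[stop - 1]),
    }


def extract_rate_table(time_courses, constants: AssayConstants | None = None,
                       **window_kwargs) -> pd.DataFrame:
    """Extract initial rates for a collection of wells into one table."""
    rows = [extract_initial_rate(tc, constants, **window_kwargs)
            for tc in time_courses]
    if not rows:
        raise ValidationError("no time courses supplied")
    return pd.DataFrame(rows, columns=list(RATE_TABLE_COLUMNS))
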