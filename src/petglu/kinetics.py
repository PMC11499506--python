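"""Patlak graphical analysis and the metabolic rate of glucose (MRGlu).

For an irreversibly trapped tracer (FDG) the Patlak linearization plots

    y(t) = C_T(t) / Cp(t)     against     x(t) = int_0^t Cp dtau / Cp(t)

where C_T is the tissue time-activity curve and Cp the plasma input
function.  After an equilibration time t* the points fall on a straight
line whose slope is the net influx constant Ki = K1*k3/(k2+k3) (mL/min/mL)
and whose intercept approximates the apparent distribution volume.

MRGlu converts Ki to a glucose flux:

    MRGlu [umol/min/100g] = Ki * PG / LC * 100

with PG the plasma glucose in umol/mL (from mg/dL via the 180.16 g/mol
molar mass of glucose) and LC the lumped constant.  Tissue density is
treated as 1 g/mL by default (configurable multiplier).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import (
    ConfigError,
    DegenerateInput,
    EmptyVOI,
    GeometryError,
    TimeGridMismatch,
)
from .imaging import DynamicPETSeries, TimeActivityCurve, VOIMask

__all__ = [
    "PatlakPoints",
    "PatlakFit",
    "MRGluResult",
    "GLUCOSE_MOLAR_MASS_G_MOL",
    "compute_tac",
    "patlak_transform",
    "fit_patlak",
    "compute_mrglu",
    "filter_negative",
    "smooth_frames",
]

GLUCOSE_MOLAR_MASS_G_MOL = 180.16
_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def glucose_mg_dl_to_umol_ml(mg_dl: float) -> float:
    """mg/dL -> umol/mL (== mmol/L): 100 mg/dL = 5.5506 umol/mL."""
    return float(mg_dl) * 10.0 / GLUCOSE_MOLAR_MASS_G_MOL


@dataclass
class PatlakPoints:
    """Patlak coordinates with the frame mid-times they came from.

    ``dropped`` lists frame indices excluded because Cp <= 0 there.
    """

    t_min: np.ndarray
    x_min: np.ndarray
    y: np.ndarray
    dropped: list[int] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.t_min)

    @property
    def xy(self) -> np.ndarray:
        return np.column_stack([self.x_min, self.y])


@dataclass
class PatlakFit:
    """Result of the late-time linear regression of the Patlak plot."""

    Ki: float                    # slope, mL/min/mL
    intercept: float             # unitless apparent distribution volume
    t_star_min: float
    n_points: int
    r_squared: float
    points: PatlakPoints

    def __post_init__(self):
        if self.n_points < 2:
            raise DegenerateInput("Patlak fit needs at least 2 points")


@dataclass
class MRGluResult:
    value: float                 # umol/min/100g
    district: str
    Ki: float
    plasma_glucose_mg_dl: float
    lumped_constant: float
    negative: bool = False

    def __post_init__(self):
        self.negative = bool(self.value < 0)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def compute_tac(series: DynamicPETSeries, voi: VOIMask) -> TimeActivityCurve:
    """Arithmetic mean activity over the VOI per frame, versus mid-times in
    minutes.  The series must be decay-corrected and share the VOI's grid."""
    if not series.decay_corrected:
        raise ConfigError("kinetic analysis requires a decay-corrected series")
    if not series.geometry.approx_equal(voi.geometry):
        raise GeometryError("VOI and PET series are not on the same grid")
    mask = voi.mask
    if not mask.any():
        raise EmptyVOI("cannot compute a TAC over an empty VOI")
    activity = series.voxels[mask, :].mean(axis=0)
    return TimeActivityCurve(
        series.schedule.mid_times_min, activity, int(mask.sum()), label=voi.label
    )


def patlak_transform(
    tissue: TimeActivityCurve, input_fn: TimeActivityCurve
) -> PatlakPoints:
    """Map tissue and input TACs to Patlak coordinates.

    The running integral of Cp uses the trapezoidal rule over frame
    mid-times, with a (t=0, Cp=0) sample prepended when the first mid-time is
    after injection (activity is zero at injection time).  Frames with
    Cp <= 0 are dropped and reported.
    """
    if len(tissue) != len(input_fn) or not np.allclose(
        tissue.mid_times_min, input_fn.mid_times_min, atol=1e-9
    ):
        raise TimeGridMismatch("tissue and input TACs use different mid-time grids")
    t = np.asarray(input_fn.mid_times_min, dtype=float)
    cp = np.asarray(input_fn.activity, dtype=float)
    ct = np.asarray(tissue.activity, dtype=float)
    if t[0] > 0:
        t_int = np.concatenate([[0.0], t])
        cp_int = np.concatenate([[0.0], cp])
    else:
        t_int, cp_int = t, cp
    integral = np.concatenate(
        [[0.0], np.cumsum(np.diff(t_int) * (cp_int[1:] + cp_int[:-1]) / 2.0)]
    )
    integral = integral[-len(t):]
    usable = cp > 0
    dropped = [int(i) for i in np.flatnonzero(~usable)]
    if not usable.any():
        raise DegenerateInput("input function is non-positive at every frame")
    return PatlakPoints(
        t_min=t[usable],
        x_min=integral[usable] / cp[usable],
        y=ct[usable] / cp[usable],
        dropped=dropped,
    )


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    # centered form: exact zero slope for constant y
    xm, ym = x.mean(), y.mean()
    dx, dy = x - xm, y - ym
    slope = float(np.dot(dx, dy) / np.dot(dx, dx))
    intercept = ym - slope * xm
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum(resid**2)) / ss_tot
    return float(slope), float(intercept), float(np.clip(r2, 0.0, 1.0))


def _max_rel_residual(x: np.ndarray, y: np.ndarray) -> float:
    slope, intercept, _ = _ols_line(x, y)
    pred = slope * x + intercept
    denom = np.where(np.abs(y) > 1e-12, np.abs(y), 1e-12)
    return float(np.max(np.abs(y - pred) / denom))


def fit_patlak(points: PatlakPoints, t_star_min: float | str = 10.0) -> PatlakFit:
    """Ordinary least squares of y on x over points at or after t*.

    ``t_star_min="auto"`` chooses the earliest t* whose fit over [t*, end]
    has a maximum absolute relative residual <= 5% (falling back, when no
    candidate qualifies, to the t* minimising that residual with >= 3
    points).
    """
    t, x, y = points.t_min, points.x_min, points.y
    if t_star_min == "auto":
        best, best_res = None, np.inf
        for cand in t[:-1]:
            sel = t >= cand
            if sel.sum() < 2:
                break
            res = _max_rel_residual(x[sel], y[sel])
            if res <= 0.05:
                best = float(cand)
                break
            if sel.sum() >= 3 and res < best_res:
                best, best_res = float(cand), res
        if best is None:
            raise DegenerateInput("auto t* found no usable linear segment")
        t_star = best
    else:
        t_star = float(t_star_min)
    sel = t >= t_star
    if sel.sum() < 2:
        raise DegenerateInput(
            f"only {int(sel.sum())} Patlak points at or after t*={t_star:g} min"
        )
    slope, intercept, r2 = _ols_line(x[sel], y[sel])
    return PatlakFit(
        Ki=slope,
        intercept=intercept,
        t_star_min=t_star,
        n_points=int(sel.sum()),
        r_squared=r2,
        points=points,
    )


def compute_mrglu(
    fit: PatlakFit,
    plasma_glucose_mg_dl: float,
    lumped_constant: float = 1.0,
    district: str = "custom",
    tissue_density_g_ml: float = 1.0,
) -> MRGluResult:
    """MRGlu = Ki * PG[umol/mL] / LC * 100, in umol/min/100g."""
    if plasma_glucose_mg_dl <= 0:
        raise ConfigError("plasma glucose must be > 0 mg/dL")
    if lumped_constant <= 0:
        raise ConfigError("lumped constant must be > 0")
    if tissue_density_g_ml <= 0:
        raise ConfigError("tissue density must be > 0 g/mL")
    pg = glucose_mg_dl_to_umol_ml(plasma_glucose_mg_dl)
    value = fit.Ki * pg / lumped_constant * 100.0 / tissue_density_g_ml
    return MRGluResult(
        value=float(value),
        district=district,
        Ki=fit.Ki,
        plasma_glucose_mg_dl=float(plasma_glucose_mg_dl),
        lumped_constant=float(lumped_constant),
    )


def filter_negative(
    results: list[MRGluResult],
) -> tuple[list[MRGluResult], list[MRGluResult]]:
    """Partition results into (kept: value >= 0, excluded: value < 0).

    Negative MRGlu arises from the Patlak model when the input-function slope
    dominates the VOI concentration; such values are excluded from clinical
    analysis rather than corrected.
    """
    kept = [r for r in results if r.value >= 0]
    excluded = [r for r in results if r.value < 0]
    return kept, excluded


def smooth_frames(series: DynamicPETSeries, fwhm_mm: float) -> DynamicPETSeries:
    """Per-frame isotropic Gaussian smoothing (noise pre-processing).

    ``fwhm_mm=0`` is the identity; total activity is conserved away from the
    image edges."""
    if fwhm_mm < 0:
        raise ConfigError("fwhm_mm must be >= 0")
    if fwhm_mm == 0:
        return series
    sigma_vox = [fwhm_mm * _FWHM_TO_SIGMA / s for s in series.geometry.spacing]
    out = np.empty_like(series.voxels, dtype=np.float64)
    for f in range(series.n_frames):
        out[..., f] = ndimage.gaussian_filter(
            np.asarray(series.voxels[..., f], dtype=np.float64),
            sigma=sigma_vox,
            mode="nearest",
        )
    return DynamicPETSeries(
        out.astype(series.voxels.dtype, copy=False),
        series.geometry,
        series.schedule,
        series.decay_corrected,
    )
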