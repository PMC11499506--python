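"""Synthetic thorax phantom and cohort generator with known ground truth.

Everything downstream (fusion, VOI extraction, Patlak, cohort statistics) is
exercised against this module: a piecewise-constant CT with air / lung /
soft-tissue / aorta / myocardium / spine compartments, a dynamic PET series
driven by an analytic plasma input function

    Cp(t) = A * t * exp(-lambda t) + B * (1 - exp(-mu t))      [kBq/cc, t min]

with blood regions (aorta lumen, left-ventricle pool) carrying Cp and tissue
regions carrying the irreversible two-tissue-compartment response

    dC1/dt = K1 Cp - (k2 + k3) C1,   dC2/dt = k3 C1,   C_T = C1 + C2,

integrated on a 1 s grid with an exponential integrator and averaged over
each acquisition frame.  Optional per-frame rigid motion and frame-duration-
scaled Gaussian noise complete the imaging side; a synthetic patient cohort
with configurable risk-factor distributions and treatment effects covers the
statistics side.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .cohort import GROUPS, RISK_FACTORS, PatientRecord
from .errors import FrameTimingMismatch, SpecError
from .imaging import (
    CTVolume,
    DynamicPETSeries,
    FrameSchedule,
    ImageGeometry,
    RigidTransform,
    ScalarVolume,
    TimeActivityCurve,
    resample_to_grid,
)
from .kinetics import glucose_mg_dl_to_umol_ml

__all__ = [
    "InputFunctionParams",
    "RegionSpec",
    "PhantomSpec",
    "PhantomTruth",
    "default_phantom_spec",
    "make_ct_phantom",
    "make_dynamic_pet_phantom",
    "apply_known_motion",
    "make_synthetic_cohort",
    "net_influx_ki",
    "RISK_FACTOR_DISTRIBUTIONS",
    "DEFAULT_PRE_MRGLU",
    "DEFAULT_GROUP_EFFECTS",
]

#: Default dynamic cardiac FDG schedule: 12x10 s, 4x30 s, 4x60 s, 10x300 s.
DEFAULT_FRAME_DURATIONS_S = (10.0,) * 12 + (30.0,) * 4 + (60.0,) * 4 + (300.0,) * 10

#: Cohort risk-factor (mean, SD) pairs in clinical units.
RISK_FACTOR_DISTRIBUTIONS = {
    "age_years": (56.9, 7.49),
    "leanM": (3.20, 1.84),
    "bmi": (31.19, 4.55),
    "waist_cm": (107.25, 9.95),
    "sbp": (126.50, 11.87),
    "dbp": (78.35, 11.03),
    "pp": (49.35, 9.24),
    "fpg": (142.15, 40.05),
    "fpins": (11.76, 6.18),
    "esr": (13.00, 12.36),
    "pcr": (3.28, 2.75),
    "pwv": (6.90, 1.25),
    "ao": (3.59, 0.41),
}

#: Pre-treatment MRGlu (mean, SD) per district and group, umol/min/100g.
DEFAULT_PRE_MRGLU = {
    "aorta": {"Group1": (-2.99, 2.94), "Group2": (-3.99, 5.16)},
    "myoc": {"Group1": (11.99, 11.91), "Group2": (11.50, 12.17)},
}

#: True additive post-minus-pre treatment effects per district and group.
DEFAULT_GROUP_EFFECTS = {
    "aorta": {"Group1": 4.08, "Group2": 3.75},
    "myoc": {"Group1": 2.86, "Group2": -0.14},
}


def net_influx_ki(k1: float, k2: float, k3: float) -> float:
    """Patlak net influx constant Ki = K1*k3/(k2+k3) (0 when k2+k3 == 0)."""
    return 0.0 if (k2 + k3) == 0 else k1 * k3 / (k2 + k3)


@dataclass(frozen=True)
class InputFunctionParams:
    """Two-term analytic blood curve: bolus passage plus slow recirculation."""

    A_kbq_cc_per_min: float = 80.0
    lambda_per_min: float = 1.5
    B_kbq_cc: float = 8.0
    mu_per_min: float = 0.3

    def __call__(self, t_min: np.ndarray) -> np.ndarray:
        t = np.asarray(t_min, dtype=float)
        return (
            self.A_kbq_cc_per_min * t * np.exp(-self.lambda_per_min * t)
            + self.B_kbq_cc * (1.0 - np.exp(-self.mu_per_min * t))
        )


@dataclass(frozen=True)
class RegionSpec:
    """One phantom compartment.

    ``shape`` is one of ``ellcyl`` (elliptic cylinder along z), ``ellipsoid``,
    ``sphere``, ``shell`` (spherical), ``tube`` (circular cylinder along z,
    optionally z-limited); geometry parameters are in mm (``center``,
    ``radius``, ``semi_axes``, ``r_inner``/``r_outer``, ``z_range``).

    ``blood=True`` regions carry the input function; others need a kinetic
    triple (K1, k2, k3) in 1/min.  ``organ`` regions must be pairwise
    disjoint and win over background regions when painting.
    """

    name: str
    shape: str
    hu: float
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    radius: float = 10.0
    semi_axes: tuple[float, float, float] = (10.0, 10.0, 10.0)
    r_inner: float = 0.0
    r_outer: float = 10.0
    z_range: tuple[float, float] | None = None
    kinetics: tuple[float, float, float] | None = None
    blood: bool = False
    organ: bool = False

    def __post_init__(self):
        if not self.blood and self.kinetics is None:
            raise SpecError(f"region '{self.name}' needs kinetics or blood=True")
        if self.kinetics is not None and any(k < 0 for k in self.kinetics):
            raise SpecError(f"region '{self.name}' has negative rate constants")
        if self.shape == "shell" and self.r_outer <= self.r_inner:
            raise SpecError(f"shell '{self.name}' needs r_outer > r_inner")

    def rasterize(self, coords: np.ndarray) -> np.ndarray:
        """Binary mask of this shape on voxel-center coordinates (..., 3)."""
        d = coords - np.asarray(self.center)
        if self.shape == "ellcyl":
            a, b, _ = self.semi_axes
            mask = (d[..., 0] / a) ** 2 + (d[..., 1] / b) ** 2 <= 1.0
        elif self.shape == "ellipsoid":
            a, b, c = self.semi_axes
            mask = ((d[..., 0] / a) ** 2 + (d[..., 1] / b) ** 2
                    + (d[..., 2] / c) ** 2) <= 1.0
        elif self.shape == "sphere":
            mask = np.linalg.norm(d, axis=-1) <= self.radius
        elif self.shape == "shell":
            r = np.linalg.norm(d, axis=-1)
            mask = (r > self.r_inner) & (r <= self.r_outer)
        elif self.shape == "tube":
            mask = d[..., 0] ** 2 + d[..., 1] ** 2 <= self.radius**2
        else:
            raise SpecError(f"unknown shape '{self.shape}'")
        if self.z_range is not None:
            z = coords[..., 2]
            mask &= (z >= self.z_range[0]) & (z <= self.z_range[1])
        return mask


def default_regions() -> tuple[RegionSpec, ...]:
    """Thorax layout on the default 256 x 256 x 128 mm field of view."""
    return (
        RegionSpec("soft_tissue", "ellcyl", hu=40.0, center=(126, 126, 62),
                   semi_axes=(110, 90, 1), kinetics=(0.10, 0.5, 0.01)),
        RegionSpec("lung_left", "ellipsoid", hu=-800.0, center=(62, 108, 62),
                   semi_axes=(36, 46, 54), kinetics=(0.02, 0.4, 0.005)),
        RegionSpec("lung_right", "ellipsoid", hu=-800.0, center=(190, 108, 62),
                   semi_axes=(36, 46, 54), kinetics=(0.02, 0.4, 0.005)),
        RegionSpec("spine", "tube", hu=300.0, center=(126, 198, 62),
                   radius=14.0, kinetics=(0.05, 0.5, 0.01)),
        RegionSpec("myocardium", "shell", hu=45.0, center=(96, 136, 62),
                   r_inner=16.0, r_outer=28.0, kinetics=(0.6, 1.2, 0.1),
                   organ=True),
        RegionSpec("left_ventricle", "sphere", hu=45.0, center=(96, 136, 62),
                   radius=16.0, blood=True, organ=True),
        # z-limited so moderate axial motion cannot push the lumen out of field
        RegionSpec("aorta", "tube", hu=50.0, center=(160, 140, 62),
                   radius=12.0, z_range=(12.0, 112.0), blood=True, organ=True),
    )


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of a synthetic acquisition."""

    geometry: ImageGeometry = field(
        default_factory=lambda: ImageGeometry((64, 64, 32), (4.0, 4.0, 4.0))
    )
    regions: tuple[RegionSpec, ...] = field(default_factory=default_regions)
    schedule: FrameSchedule = field(
        default_factory=lambda: FrameSchedule.from_durations(DEFAULT_FRAME_DURATIONS_S)
    )
    input_fn: InputFunctionParams = field(default_factory=InputFunctionParams)
    noise_cv: float = 0.0
    ref_duration_s: float = 60.0
    air_hu: float = -1000.0
    plasma_glucose_mg_dl: float = 100.0
    lumped_constant: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.noise_cv < 0:
            raise SpecError("noise_cv must be >= 0")
        if self.ref_duration_s <= 0:
            raise SpecError("ref_duration_s must be > 0")


def default_phantom_spec(**overrides) -> PhantomSpec:
    return replace(PhantomSpec(), **overrides) if overrides else PhantomSpec()


@dataclass
class PhantomTruth:
    """Ground truth accompanying a phantom: per-district masks, kinetic
    constants, MRGlu, the noiseless frame-averaged curves, applied motion."""

    geometry: ImageGeometry
    schedule: FrameSchedule
    masks: dict[str, np.ndarray]
    ki: dict[str, float]
    mrglu: dict[str, float]
    plasma_glucose_mg_dl: float
    lumped_constant: float
    input_tac: TimeActivityCurve | None = None
    region_tacs: dict[str, TimeActivityCurve] = field(default_factory=dict)
    applied_motion: list[RigidTransform] | None = None

    def mask_voi(self, name: str):
        from .imaging import VOIMask

        return VOIMask(self.masks[name], self.geometry, label=name)


# ---------------------------------------------------------------------------
# volume assembly
# ---------------------------------------------------------------------------

def _voxel_coords(geom: ImageGeometry) -> np.ndarray:
    idx = np.stack(
        np.meshgrid(*[np.arange(n, dtype=float) for n in geom.dims], indexing="ij"),
        axis=-1,
    )
    m = geom.affine[:3, :3]
    return idx @ m.T + np.asarray(geom.origin)


def _paint_regions(spec: PhantomSpec) -> dict[str, np.ndarray]:
    """Assign every voxel to at most one region (later regions win; organs
    must not overlap each other)."""
    coords = _voxel_coords(spec.geometry)
    raw = {r.name: r.rasterize(coords) for r in spec.regions}
    organs = [r for r in spec.regions if r.organ]
    for i, a in enumerate(organs):
        for b in organs[i + 1:]:
            if np.any(raw[a.name] & raw[b.name]):
                raise SpecError(f"organ regions '{a.name}' and '{b.name}' overlap")
    masks: dict[str, np.ndarray] = {}
    claimed = np.zeros(spec.geometry.dims, dtype=bool)
    for r in reversed(spec.regions):  # later regions take precedence
        m = raw[r.name] & ~claimed
        claimed |= m
        masks[r.name] = m
    return {r.name: masks[r.name] for r in spec.regions}


def _truth_tables(spec: PhantomSpec, masks) -> tuple[dict, dict]:
    ki, mrglu = {}, {}
    pg = glucose_mg_dl_to_umol_ml(spec.plasma_glucose_mg_dl)
    for r in spec.regions:
        k = 0.0 if r.blood else net_influx_ki(*r.kinetics)
        ki[r.name] = k
        mrglu[r.name] = k * pg / spec.lumped_constant * 100.0
    return ki, mrglu


def make_ct_phantom(spec: PhantomSpec | None = None) -> tuple[CTVolume, PhantomTruth]:
    """Piecewise-constant HU thorax volume plus ground-truth masks."""
    spec = spec or PhantomSpec()
    masks = _paint_regions(spec)
    hu = np.full(spec.geometry.dims, spec.air_hu, dtype=np.float32)
    for r in spec.regions:
        hu[masks[r.name]] = r.hu
    ki, mrglu = _truth_tables(spec, masks)
    truth = PhantomTruth(
        geometry=spec.geometry,
        schedule=spec.schedule,
        masks=masks,
        ki=ki,
        mrglu=mrglu,
        plasma_glucose_mg_dl=spec.plasma_glucose_mg_dl,
        lumped_constant=spec.lumped_constant,
    )
    return CTVolume(hu, spec.geometry), truth


# ---------------------------------------------------------------------------
# kinetic simulation
# ---------------------------------------------------------------------------

def _two_tissue_response(
    t_min: np.ndarray, cp: np.ndarray, k1: float, k2: float, k3: float
) -> np.ndarray:
    """C_T = C1 + C2 on the fine grid, via an exact exponential integrator
    for C1 (Cp linear within each step) and trapezoidal C2 = k3 int C1."""
    a = k2 + k3
    n = len(t_min)
    c1 = np.zeros(n)
    dt = np.diff(t_min)
    if a == 0:
        # no efflux: C1 = K1 int Cp
        c1[1:] = k1 * np.cumsum(dt * (cp[1:] + cp[:-1]) / 2.0)
    else:
        e = np.exp(-a * dt)
        f1 = (1.0 - e) / a
        f2 = (dt - f1) / a
        for i in range(n - 1):
            c0, cnext = cp[i], cp[i + 1]
            c1[i + 1] = c1[i] * e[i] + k1 * (c0 * f1[i] + (cnext - c0) * f2[i] / dt[i])
    c2 = np.zeros(n)
    c2[1:] = k3 * np.cumsum(dt * (c1[1:] + c1[:-1]) / 2.0)
    return c1 + c2


def _frame_average(t_fine_s: np.ndarray, y: np.ndarray,
                   schedule: FrameSchedule) -> np.ndarray:
    out = np.empty(len(schedule))
    for i, (a, b) in enumerate(schedule.frames):
        ts = np.linspace(a, b, max(int(round(b - a)) + 1, 5))
        vals = np.interp(ts, t_fine_s, y)
        out[i] = np.trapezoid(vals, ts) / (b - a)
    return out


def region_frame_curves(spec: PhantomSpec) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Noiseless frame-averaged activity per region, plus the frame-averaged
    input function, on the spec's schedule."""
    t_fine_s = np.arange(0.0, spec.schedule.end_s + 1.0, 1.0)
    t_fine_min = t_fine_s / 60.0
    cp_fine = spec.input_fn(t_fine_min)
    cp_frames = _frame_average(t_fine_s, cp_fine, spec.schedule)
    curves: dict[str, np.ndarray] = {}
    for r in spec.regions:
        if r.blood:
            curves[r.name] = cp_frames.copy()
        else:
            ct_fine = _two_tissue_response(t_fine_min, cp_fine, *r.kinetics)
            curves[r.name] = _frame_average(t_fine_s, ct_fine, spec.schedule)
    return curves, cp_frames


def make_dynamic_pet_phantom(
    spec: PhantomSpec | None = None,
) -> tuple[DynamicPETSeries, PhantomTruth]:
    """Dynamic PET series with known kinetics; deterministic given the spec
    (noise is seeded by ``spec.seed``)."""
    spec = spec or PhantomSpec()
    masks = _paint_regions(spec)
    curves, cp_frames = region_frame_curves(spec)
    dims = spec.geometry.dims
    n_frames = len(spec.schedule)
    vox = np.zeros((*dims, n_frames), dtype=np.float64)
    for name, mask in masks.items():
        vox[mask, :] = curves[name]
    if spec.noise_cv > 0:
        rng = np.random.default_rng(spec.seed)
        scale = np.sqrt(spec.ref_duration_s / spec.schedule.durations_s)
        for f in range(n_frames):
            sd = spec.noise_cv * np.abs(vox[..., f]) * scale[f]
            vox[..., f] += rng.normal(0.0, 1.0, dims) * sd
    ki, mrglu = _truth_tables(spec, masks)
    mids = spec.schedule.mid_times_min
    truth = PhantomTruth(
        geometry=spec.geometry,
        schedule=spec.schedule,
        masks=masks,
        ki=ki,
        mrglu=mrglu,
        plasma_glucose_mg_dl=spec.plasma_glucose_mg_dl,
        lumped_constant=spec.lumped_constant,
        input_tac=TimeActivityCurve(mids, cp_frames, 1, label="input_function"),
        region_tacs={
            name: TimeActivityCurve(mids, c, max(int(masks[name].sum()), 1), label=name)
            for name, c in curves.items()
        },
    )
    series = DynamicPETSeries(vox.astype(np.float32), spec.geometry, spec.schedule, True)
    return series, truth


def apply_known_motion(
    series: DynamicPETSeries, transforms: Sequence[RigidTransform]
) -> DynamicPETSeries:
    """Resample each frame under its rigid transform (linear interpolation);
    the test-harness inverse of motion correction."""
    if len(transforms) != series.n_frames:
        raise FrameTimingMismatch(
            f"{len(transforms)} transforms for {series.n_frames} frames"
        )
    out = np.empty_like(series.voxels, dtype=np.float64)
    for f, tr in enumerate(transforms):
        frame = ScalarVolume(series.voxels[..., f], series.geometry)
        out[..., f] = resample_to_grid(frame, series.geometry, tr, "linear").voxels
    return DynamicPETSeries(
        out.astype(series.voxels.dtype, copy=False),
        series.geometry,
        series.schedule,
        series.decay_corrected,
    )


# ---------------------------------------------------------------------------
# synthetic cohort
# ---------------------------------------------------------------------------

def make_synthetic_cohort(
    n_per_group: int,
    effects: dict | None = None,
    seed: int = 0,
    risk_factor_params: dict | None = None,
    pre_params: dict | None = None,
    post_noise_sd: float = 3.0,
    regression_link: dict | None = None,
) -> list[PatientRecord]:
    """Draw a synthetic two-group patient cohort.

    Risk factors are independent Gaussians with the configured (mean, SD)
    per factor; pre-treatment MRGlu is Gaussian per district and group;
    post = pre + group effect + N(0, post_noise_sd).

    ``regression_link`` optionally replaces a district's pre values with a
    linear function of the risk factors plus noise, e.g.
    ``{"district": "aorta", "intercept": 1.0, "coefficients": {"bmi": 0.5},
    "noise_sd": 1.0}`` -- used for regression-recovery experiments.
    """
    if n_per_group < 1:
        raise SpecError("n_per_group must be >= 1")
    effects = effects if effects is not None else DEFAULT_GROUP_EFFECTS
    rf_params = risk_factor_params or RISK_FACTOR_DISTRIBUTIONS
    pre_params = pre_params or DEFAULT_PRE_MRGLU
    rng = np.random.default_rng(seed)
    records: list[PatientRecord] = []
    n_total = 2 * n_per_group
    groups = [GROUPS[0]] * n_per_group + [GROUPS[1]] * n_per_group

    factors = {
        name: rng.normal(*rf_params[name], size=n_total) for name in RISK_FACTORS
    }
    pre = {}
    for district in ("aorta", "myoc"):
        vals = np.empty(n_total)
        for g in GROUPS:
            sel = np.asarray([gi == g for gi in groups])
            mean, sd = pre_params[district][g]
            vals[sel] = rng.normal(mean, sd, size=int(sel.sum()))
        pre[district] = vals
    if regression_link is not None:
        district = regression_link["district"]
        lin = np.full(n_total, float(regression_link.get("intercept", 0.0)))
        for name, coef in regression_link["coefficients"].items():
            lin += float(coef) * factors[name]
        noise_sd = float(regression_link.get("noise_sd", 0.0))
        if noise_sd > 0:
            lin += rng.normal(0.0, noise_sd, size=n_total)
        pre[district] = lin
    post = {}
    for district in ("aorta", "myoc"):
        eff = np.asarray([effects[district][g] for g in groups], dtype=float)
        noise = rng.normal(0.0, post_noise_sd, size=n_total) if post_noise_sd > 0 else 0.0
        post[district] = pre[district] + eff + noise

    for i in range(n_total):
        records.append(
            PatientRecord(
                id=f"P{i + 1:04d}",
                group=groups[i],
                mrglu_aorta_pre=float(pre["aorta"][i]),
                mrglu_aorta_post=float(post["aorta"][i]),
                mrglu_myoc_pre=float(pre["myoc"][i]),
                mrglu_myoc_post=float(post["myoc"][i]),
                **{name: float(factors[name][i]) for name in RISK_FACTORS},
            )
        )
    return records
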