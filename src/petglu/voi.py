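"""Seed-point VOI extraction for vessels (on CT) and uptake regions (on PET).

The vessel extractor reproduces the one-click circular aorta VOI workflow:
region growing inside an HU window from a user seed, then on each axial slice
the grown cross-section is replaced by the least-squares circle of its
boundary, tracking the vessel centerline up and down until the configured
axial extent is covered or the cross-section stops looking like a vessel
(circularity drop).

The uptake extractor thresholds at a fraction of the local maximum around the
seed on a task-appropriate temporal average: late frames for trapped-tracer
tissue (myocardium), early blood-pool frames for the left-ventricle input
function region.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure

from .errors import ConfigError, EmptyVOI, LeakDetected, SeedOutsideRange
from .imaging import (
    CTVolume,
    DynamicPETSeries,
    ImageGeometry,
    RigidTransform,
    VOIMask,
    resample_to_grid,
    time_average,
)

__all__ = [
    "VesselVOIParams",
    "UptakeVOIParams",
    "extract_vessel_voi",
    "extract_uptake_voi",
    "map_voi",
]

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)
_STRUCT6 = ndimage.generate_binary_structure(3, 1)


@dataclass(frozen=True)
class VesselVOIParams:
    """Defaults target non-contrast blood HU and aortic calibre."""

    hu_window: tuple[float, float] = (0.0, 100.0)
    max_radius_mm: float = 25.0
    axial_extent_mm: float = 40.0
    min_circularity: float = 0.8

    def __post_init__(self):
        lo, hi = self.hu_window
        if lo >= hi:
            raise ConfigError(f"hu_window low {lo} must be < high {hi}")
        if self.max_radius_mm <= 0:
            raise ConfigError("max_radius_mm must be > 0")
        if not 0.0 <= self.min_circularity <= 1.0:
            raise ConfigError("min_circularity must lie in [0, 1]")


@dataclass(frozen=True)
class UptakeVOIParams:
    threshold_fraction: float = 0.5
    search_radius_mm: float = 60.0
    frames_used: str | None = None  # "early" | "late" | None (per-district default)
    early_window_min: float = 2.0
    late_window_min: float = 10.0

    def __post_init__(self):
        if not 0.0 < self.threshold_fraction < 1.0:
            raise ConfigError("threshold_fraction must lie in (0, 1)")
        if self.search_radius_mm <= 0:
            raise ConfigError("search_radius_mm must be > 0")


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _seed_index(geometry: ImageGeometry, seed_mm) -> tuple[int, int, int]:
    idx = geometry.physical_to_index(np.asarray(seed_mm, dtype=float))
    if not geometry.contains_index(idx):
        raise SeedOutsideRange(f"seed {tuple(seed_mm)} mm lies outside the image field")
    return tuple(int(round(v)) for v in idx)


def _fit_circle(xy_mm: np.ndarray) -> tuple[np.ndarray, float]:
    """Least-squares (Kasa) circle through a set of 2D points, in mm."""
    x, y = xy_mm[:, 0], xy_mm[:, 1]
    a = np.column_stack([2 * x, 2 * y, np.ones_like(x)])
    b = x**2 + y**2
    sol, *_ = np.linalg.lstsq(a, b, rcond=None)
    cx, cy, c = sol
    r = float(np.sqrt(max(c + cx**2 + cy**2, 0.0)))
    return np.array([cx, cy]), r


def _circularity(region2d: np.ndarray, px_mm: float) -> float:
    """4*pi*A / P^2 of a 2D binary region (1.0 for a perfect disk)."""
    area = region2d.sum() * px_mm**2
    perim = measure.perimeter(region2d) * px_mm
    if perim == 0:
        return 1.0  # single pixel
    return float(min(4.0 * np.pi * area / perim**2, 1.0))


def _boundary_pixels(region2d: np.ndarray) -> np.ndarray:
    eroded = ndimage.binary_erosion(region2d, ndimage.generate_binary_structure(2, 1))
    boundary = region2d & ~eroded
    return np.argwhere(boundary)


def _slice_component(plane: np.ndarray, guide_xy: tuple[int, int]) -> np.ndarray | None:
    """2D 8-connected component of ``plane`` containing (or nearest by
    centroid to, if overlap-guided tracking fails) the guide pixel."""
    labels, n = ndimage.label(plane, structure=np.ones((3, 3), dtype=bool))
    if n == 0:
        return None
    lab = labels[guide_xy]
    if lab == 0:
        return None
    return labels == lab


# ---------------------------------------------------------------------------
# vessel VOI (CT)
# ---------------------------------------------------------------------------

def extract_vessel_voi(
    ct: CTVolume,
    seed_mm,
    params: VesselVOIParams = VesselVOIParams(),
    label: str = "aorta",
) -> VOIMask:
    """Extract a tubular vessel VOI from one seed click on the CT.

    Steps: 26-connected region growing within ``hu_window`` from the seed;
    per-axial-slice replacement of the cross-section by its best-fit boundary
    circle clipped to ``max_radius_mm``; centerline tracking in both axial
    directions until ``axial_extent_mm`` (total span) is covered or slice
    circularity drops below ``min_circularity``.
    """
    lo, hi = params.hu_window
    seed_idx = _seed_index(ct.geometry, seed_mm)
    hu_seed = float(ct.voxels[seed_idx])
    if not lo <= hu_seed <= hi:
        raise SeedOutsideRange(
            f"seed HU {hu_seed:.0f} outside window ({lo:.0f}, {hi:.0f})"
        )
    sx, sy, sz = ct.geometry.spacing
    px = float(np.sqrt(sx * sy))  # in-plane pixel scale (near-isotropic assumed)

    in_window = (ct.voxels >= lo) & (ct.voxels <= hi)
    labels, _ = ndimage.label(in_window, structure=_STRUCT26)
    region = labels == labels[seed_idx]

    x0, y0, z0 = seed_idx
    seed_plane = _slice_component(region[:, :, z0], (x0, y0))
    if seed_plane is None:
        raise SeedOutsideRange("seed voxel not inside the grown region")
    eq_radius = np.sqrt(seed_plane.sum() * sx * sy / np.pi)
    if eq_radius > params.max_radius_mm:
        raise LeakDetected(
            f"seed-slice equivalent radius {eq_radius:.1f} mm exceeds "
            f"max_radius_mm {params.max_radius_mm:.1f}"
        )

    nz = ct.geometry.dims[2]
    half_extent = params.axial_extent_mm / 2.0
    out = np.zeros(ct.geometry.dims, dtype=bool)
    xs, ys = np.meshgrid(
        np.arange(ct.geometry.dims[0]) * sx,
        np.arange(ct.geometry.dims[1]) * sy,
        indexing="ij",
    )

    def accept_slice(z: int, plane: np.ndarray, fallback_center: tuple[int, int]):
        """Replace the slice cross-section by its fitted circle; returns the
        circle center in pixel indices for centerline tracking."""
        bpx = _boundary_pixels(plane)
        if len(bpx) >= 3:
            center_mm, r_mm = _fit_circle(bpx * np.array([sx, sy]))
            # boundary voxel centres sit ~half a voxel inside the true edge
            r_mm += px / 2.0
        else:  # tiny cross-section: fall back to centroid + equivalent radius
            cx, cy = ndimage.center_of_mass(plane)
            center_mm = np.array([cx * sx, cy * sy])
            r_mm = max(np.sqrt(plane.sum() * sx * sy / np.pi), px / 2.0)
        r_mm = min(r_mm, params.max_radius_mm)
        disk = (xs - center_mm[0]) ** 2 + (ys - center_mm[1]) ** 2 <= r_mm**2
        out[:, :, z] = disk
        ci = (int(round(center_mm[0] / sx)), int(round(center_mm[1] / sy)))
        if not (0 <= ci[0] < plane.shape[0] and 0 <= ci[1] < plane.shape[1]):
            ci = fallback_center
        return ci

    center0 = accept_slice(z0, seed_plane, (x0, y0))
    for step in (1, -1):
        guide = center0
        z = z0 + step
        while 0 <= z < nz and abs(z - z0) * sz <= half_extent:
            plane = _slice_component(region[:, :, z], guide)
            if plane is None:
                break
            if _circularity(plane, px) < params.min_circularity:
                break
            guide = accept_slice(z, plane, guide)
            z += step

    out[seed_idx] = True  # seed containment guarantee
    comp_labels, _ = ndimage.label(out, structure=_STRUCT26)
    out = comp_labels == comp_labels[seed_idx]
    return VOIMask(out, ct.geometry, label=label, seed=tuple(np.asarray(seed_mm, float)))


# ---------------------------------------------------------------------------
# uptake VOI (PET)
# ---------------------------------------------------------------------------

def _frame_window(series: DynamicPETSeries, which: str, params: UptakeVOIParams) -> list[int]:
    mids = series.schedule.mid_times_min
    if which == "early":
        idx = np.flatnonzero(mids <= params.early_window_min)
    elif which == "late":
        idx = np.flatnonzero(mids >= mids[-1] - params.late_window_min)
    else:
        raise ConfigError(f"unknown frame window '{which}'")
    if len(idx) == 0:
        idx = np.array([0]) if which == "early" else np.array([len(mids) - 1])
    return list(idx)


def extract_uptake_voi(
    pet: DynamicPETSeries,
    seed_mm,
    params: UptakeVOIParams = UptakeVOIParams(),
    district: str = "myocardium",
) -> VOIMask:
    """Threshold-based VOI around a seed on a temporal-average PET image.

    ``myocardium``: mean of the late frames; voxels within
    ``search_radius_mm`` of the seed with activity >= threshold_fraction x
    local maximum; largest (seed-preferring) connected component; one binary
    closing.  ``left_ventricle``: same rule on the mean of the early
    blood-pool frames, then eroded by one voxel to limit myocardial spill-in.
    """
    if district not in ("myocardium", "left_ventricle"):
        raise ConfigError(f"unknown district '{district}'")
    window = params.frames_used or ("early" if district == "left_ventricle" else "late")
    frames = _frame_window(pet, window, params)
    mean_img = time_average(pet, frames).voxels

    seed_idx = _seed_index(pet.geometry, seed_mm)
    geom = pet.geometry
    grid = np.stack(
        np.meshgrid(*[np.arange(n) for n in geom.dims], indexing="ij"), axis=-1
    ).reshape(-1, 3)
    phys = geom.index_to_physical(grid.astype(float)).reshape(*geom.dims, 3)
    dist = np.linalg.norm(phys - np.asarray(seed_mm, dtype=float), axis=-1)
    sphere = dist <= params.search_radius_mm

    local_max = float(mean_img[sphere].max())
    if local_max <= 0:
        raise EmptyVOI("no positive activity within the search radius")
    candidate = sphere & (mean_img >= params.threshold_fraction * local_max)
    if not candidate.any():
        raise EmptyVOI(
            f"threshold {params.threshold_fraction:.3f} x local max left no voxels"
        )
    labels, n = ndimage.label(candidate, structure=_STRUCT26)
    if labels[seed_idx] != 0:
        comp = labels == labels[seed_idx]
    else:
        sizes = ndimage.sum_labels(candidate, labels, index=np.arange(1, n + 1))
        comp = labels == (int(np.argmax(sizes)) + 1)
    comp = ndimage.binary_closing(comp, structure=_STRUCT6, iterations=1)
    if district == "left_ventricle":
        comp = ndimage.binary_erosion(comp, structure=_STRUCT6, iterations=1)
    if comp.sum() < 2:
        raise EmptyVOI(f"{district} VOI degenerate ({int(comp.sum())} voxel)")
    # keep a single connected component (prefer the one holding the seed)
    labels, n = ndimage.label(comp, structure=_STRUCT26)
    if n > 1:
        if labels[seed_idx] != 0:
            comp = labels == labels[seed_idx]
        else:
            sizes = ndimage.sum_labels(comp, labels, index=np.arange(1, n + 1))
            comp = labels == (int(np.argmax(sizes)) + 1)
    return VOIMask(comp, geom, label=district, seed=tuple(np.asarray(seed_mm, float)))


# ---------------------------------------------------------------------------
# cross-space mapping
# ---------------------------------------------------------------------------

def map_voi(voi: VOIMask, transform: RigidTransform, target: ImageGeometry) -> VOIMask:
    """Nearest-neighbour resample of a mask onto another grid; ``transform``
    maps target physical space into the VOI's space."""
    from .imaging import ScalarVolume

    vol = ScalarVolume(voi.mask.astype(np.float64), voi.geometry)
    res = resample_to_grid(vol, target, transform, "nearest")
    mask = res.voxels > 0.5
    if not mask.any():
        raise EmptyVOI(f"VOI '{voi.label}' maps entirely outside the target grid")
    return VOIMask(mask, target, label=voi.label, seed=voi.seed)
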