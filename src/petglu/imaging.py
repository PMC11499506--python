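"""Domain types and I/O for dynamic PET, CT, VOI masks and time-activity curves.

Conventions
-----------
* Voxel indices are 0-based and arrays are indexed ``[x, y, z]`` (and ``[..., t]``
  for dynamic series).
* Physical position of voxel ``i`` is ``origin + direction @ (i * spacing)``,
  all in millimetres.
* Frame timing is carried in seconds post-injection; kinetic analysis converts
  to minutes.
* Rigid transforms map points of a *target* (output) physical space into the
  *source* (input) space, which is the convention resampling needs.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from typing import Sequence

import nibabel as nib
import numpy as np
import SimpleITK as sitk

from .errors import (
    ConfigError,
    EmptyVOI,
    FrameTimingMismatch,
    GeometryError,
    NotDynamic,
    NotStatic,
)

__all__ = [
    "ImageGeometry",
    "FrameSchedule",
    "DynamicPETSeries",
    "CTVolume",
    "ScalarVolume",
    "VOIMask",
    "TimeActivityCurve",
    "RigidTransform",
    "read_dynamic_pet",
    "write_dynamic_pet",
    "read_ct",
    "write_ct",
    "read_mask",
    "write_mask",
    "read_tac",
    "write_tac",
    "resample_to_grid",
    "time_average",
]

_ORTHO_TOL = 1e-6
HU_MIN, HU_MAX = -1100.0, 3100.0

TIMING_KEY = "FrameTimesStartEnd"
DECAY_KEY = "DecayCorrected"


# ---------------------------------------------------------------------------
# geometry and transforms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ImageGeometry:
    """Sampling grid of a 3D image: dims (voxels), spacing/origin (mm),
    direction (columns are the axis cosines)."""

    dims: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self):
        object.__setattr__(self, "dims", tuple(int(d) for d in self.dims))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        d = np.asarray(self.direction, dtype=float).reshape(3, 3)
        object.__setattr__(self, "direction", d)
        if any(n < 1 for n in self.dims):
            raise GeometryError(f"dims must be >= 1, got {self.dims}")
        if any(s <= 0 for s in self.spacing):
            raise GeometryError(f"spacings must be > 0, got {self.spacing}")
        if not np.allclose(d.T @ d, np.eye(3), atol=_ORTHO_TOL):
            raise GeometryError("direction matrix is not orthonormal")
        if not np.isclose(np.linalg.det(d), 1.0, atol=_ORTHO_TOL):
            raise GeometryError("direction matrix must have determinant +1")

    @property
    def affine(self) -> np.ndarray:
        """4x4 voxel-index -> physical-mm affine."""
        a = np.eye(4)
        a[:3, :3] = self.direction @ np.diag(self.spacing)
        a[:3, 3] = self.origin
        return a

    def index_to_physical(self, index: Sequence[float]) -> np.ndarray:
        idx = np.atleast_2d(np.asarray(index, dtype=float))
        pts = (self.affine[:3, :3] @ idx.T).T + np.asarray(self.origin)
        return pts[0] if np.ndim(index) == 1 else pts

    def physical_to_index(self, point: Sequence[float]) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(point, dtype=float)) - np.asarray(self.origin)
        idx = (np.linalg.inv(self.affine[:3, :3]) @ pts.T).T
        return idx[0] if np.ndim(point) == 1 else idx

    def contains_index(self, index: Sequence[float]) -> bool:
        idx = np.asarray(index, dtype=float)
        return bool(np.all(idx > -0.5) and np.all(idx < np.asarray(self.dims) - 0.5))

    def approx_equal(self, other: "ImageGeometry", tol_mm: float = 1e-3) -> bool:
        return (
            self.dims == other.dims
            and np.allclose(self.spacing, other.spacing, atol=tol_mm)
            and np.allclose(self.origin, other.origin, atol=tol_mm)
            and np.allclose(self.direction, other.direction, atol=1e-6)
        )

    @classmethod
    def from_affine(cls, affine: np.ndarray, dims: Sequence[int]) -> "ImageGeometry":
        m = np.asarray(affine, dtype=float)[:3, :3]
        spacing = np.linalg.norm(m, axis=0)
        direction = m / spacing
        return cls(tuple(dims), tuple(spacing), tuple(affine[:3, 3]), direction)


@dataclass(frozen=True)
class RigidTransform:
    """Rigid map ``T(p) = R (p - c) + c + t`` in physical mm.

    Used for resampling with the target-to-source convention: the output
    voxel at physical point ``p`` samples the input image at ``T(p)``.
    """

    matrix: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float).reshape(3, 3)
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "translation", tuple(float(v) for v in self.translation))
        object.__setattr__(self, "center", tuple(float(v) for v in self.center))
        if not np.allclose(m.T @ m, np.eye(3), atol=1e-6) or not np.isclose(
            np.linalg.det(m), 1.0, atol=1e-6
        ):
            raise GeometryError("rotation matrix must be orthonormal with det +1")

    # -- constructors -------------------------------------------------------
    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    @classmethod
    def from_euler(
        cls,
        angles_deg: Sequence[float] = (0.0, 0.0, 0.0),
        translation: Sequence[float] = (0.0, 0.0, 0.0),
        center: Sequence[float] = (0.0, 0.0, 0.0),
    ) -> "RigidTransform":
        """ZYX intrinsic Euler angles in degrees (the ITK Euler3D convention)."""
        t = sitk.Euler3DTransform()
        t.SetCenter([float(c) for c in center])
        t.SetRotation(*np.deg2rad(np.asarray(angles_deg, dtype=float)))
        t.SetTranslation([float(v) for v in translation])
        return cls.from_sitk(t)

    @classmethod
    def from_sitk(cls, t: sitk.Transform) -> "RigidTransform":
        try:
            t = t.Downcast()
        except AttributeError:  # already a concrete transform type
            pass
        if isinstance(t, sitk.CompositeTransform):
            out = cls.identity()
            for i in range(t.GetNumberOfTransforms()):
                out = out.compose(cls.from_sitk(t.GetNthTransform(i)))
            return out
        m = np.asarray(t.GetMatrix(), dtype=float).reshape(3, 3)
        return cls(m, tuple(t.GetTranslation()), tuple(t.GetCenter()))

    def to_sitk(self) -> sitk.AffineTransform:
        t = sitk.AffineTransform(3)
        t.SetCenter(self.center)
        t.SetMatrix([float(v) for v in self.matrix.ravel()])
        t.SetTranslation(self.translation)
        return t

    # -- algebra ------------------------------------------------------------
    def apply(self, points: Sequence[float]) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points, dtype=float))
        c = np.asarray(self.center)
        out = (self.matrix @ (p - c).T).T + c + np.asarray(self.translation)
        return out[0] if np.ndim(points) == 1 else out

    def _offset(self) -> np.ndarray:
        """Offset b of the equivalent center-free form T(p) = R p + b."""
        c = np.asarray(self.center)
        return c + np.asarray(self.translation) - self.matrix @ c

    def inverse(self) -> "RigidTransform":
        rinv = self.matrix.T
        return RigidTransform(rinv, tuple(-rinv @ self._offset()), (0.0, 0.0, 0.0))

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return ``T`` with ``T(p) = self(other(p))``."""
        r = self.matrix @ other.matrix
        b = self.matrix @ other._offset() + self._offset()
        return RigidTransform(r, tuple(b), (0.0, 0.0, 0.0))

    @property
    def euler_angles_deg(self) -> np.ndarray:
        t = sitk.Euler3DTransform()
        t.SetCenter(self.center)
        t.SetMatrix([float(v) for v in self.matrix.ravel()])
        return np.rad2deg([t.GetAngleX(), t.GetAngleY(), t.GetAngleZ()])

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "rotation": [float(v) for v in self.matrix.ravel()],
            "translation": list(self.translation),
            "center": list(self.center),
            "units": "mm",
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(
            np.asarray(d["rotation"], dtype=float).reshape(3, 3),
            tuple(d["translation"]),
            tuple(d.get("center", (0.0, 0.0, 0.0))),
        )


# ---------------------------------------------------------------------------
# frame timing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FrameSchedule:
    """Ordered, non-overlapping (start_s, end_s) acquisition frames."""

    frames: tuple[tuple[float, float], ...]

    def __post_init__(self):
        frames = tuple((float(a), float(b)) for a, b in self.frames)
        object.__setattr__(self, "frames", frames)
        if not frames:
            raise FrameTimingMismatch("schedule has no frames")
        for a, b in frames:
            if b <= a:
                raise FrameTimingMismatch(f"frame end {b} not after start {a}")
        starts = [a for a, _ in frames]
        if sorted(starts) != starts:
            raise FrameTimingMismatch("frames must be sorted by start time")
        for (_, e0), (s1, _) in zip(frames, frames[1:]):
            if s1 < e0 - 1e-9:
                raise FrameTimingMismatch("frames overlap")
        mids = self.mid_times_s
        if np.any(np.diff(mids) <= 0):
            raise FrameTimingMismatch("frame mid-times must strictly increase")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def mid_times_s(self) -> np.ndarray:
        return np.array([(a + b) / 2.0 for a, b in self.frames])

    @property
    def mid_times_min(self) -> np.ndarray:
        return self.mid_times_s / 60.0

    @property
    def durations_s(self) -> np.ndarray:
        return np.array([b - a for a, b in self.frames])

    @property
    def end_s(self) -> float:
        return self.frames[-1][1]

    @classmethod
    def from_durations(cls, durations_s: Sequence[float], start_s: float = 0.0) -> "FrameSchedule":
        frames, t = [], float(start_s)
        for d in durations_s:
            frames.append((t, t + float(d)))
            t += float(d)
        return cls(tuple(frames))


# ---------------------------------------------------------------------------
# image containers
# ---------------------------------------------------------------------------

@dataclass
class ScalarVolume:
    """A plain 3D image on a geometry (e.g. a time-averaged PET frame)."""

    voxels: np.ndarray
    geometry: ImageGeometry

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise NotStatic(f"expected a 3D array, got ndim={self.voxels.ndim}")
        if tuple(self.voxels.shape) != self.geometry.dims:
            raise GeometryError(
                f"array shape {self.voxels.shape} != geometry dims {self.geometry.dims}"
            )


@dataclass
class CTVolume(ScalarVolume):
    """CT volume in Hounsfield units."""

    def __post_init__(self):
        super().__post_init__()
        lo, hi = float(np.min(self.voxels)), float(np.max(self.voxels))
        if lo < HU_MIN or hi > HU_MAX:
            raise GeometryError(f"HU values [{lo}, {hi}] outside [{HU_MIN}, {HU_MAX}]")


@dataclass
class DynamicPETSeries:
    """4D decay-corrected activity (kBq/cc), indexed [x, y, z, frame]."""

    voxels: np.ndarray
    geometry: ImageGeometry
    schedule: FrameSchedule
    decay_corrected: bool = True

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 4:
            raise NotDynamic(f"expected a 4D array, got ndim={self.voxels.ndim}")
        if tuple(self.voxels.shape[:3]) != self.geometry.dims:
            raise GeometryError(
                f"spatial shape {self.voxels.shape[:3]} != geometry dims {self.geometry.dims}"
            )
        if self.voxels.shape[3] != len(self.schedule):
            raise FrameTimingMismatch(
                f"{self.voxels.shape[3]} frames in volume vs {len(self.schedule)} timing rows"
            )
        if not np.all(np.isfinite(self.voxels)):
            raise GeometryError("activity values must be finite")

    @property
    def n_frames(self) -> int:
        return self.voxels.shape[3]

    def frame(self, i: int) -> ScalarVolume:
        return ScalarVolume(np.ascontiguousarray(self.voxels[..., i]), self.geometry)


@dataclass
class VOIMask:
    """Binary region on a reference grid with a district label."""

    mask: np.ndarray
    geometry: ImageGeometry
    label: str = "custom"
    seed: tuple[float, float, float] | None = None

    def __post_init__(self):
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.ndim != 3:
            raise GeometryError("mask must be 3D")
        if tuple(self.mask.shape) != self.geometry.dims:
            raise GeometryError(
                f"mask shape {self.mask.shape} != geometry dims {self.geometry.dims}"
            )
        if not self.mask.any():
            raise EmptyVOI(f"VOI '{self.label}' has no foreground voxels")

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())

    @property
    def volume_ml(self) -> float:
        return self.voxel_count * float(np.prod(self.geometry.spacing)) / 1000.0


@dataclass
class TimeActivityCurve:
    """Mean VOI activity (kBq/cc) per frame, against frame mid-times (min)."""

    mid_times_min: np.ndarray
    activity: np.ndarray
    voxel_count: int
    label: str = "custom"

    def __post_init__(self):
        self.mid_times_min = np.asarray(self.mid_times_min, dtype=float)
        self.activity = np.asarray(self.activity, dtype=float)
        if self.mid_times_min.shape != self.activity.shape:
            raise GeometryError("mid_times and activity must have equal length")
        if np.any(np.diff(self.mid_times_min) <= 0):
            raise GeometryError("mid-times must strictly increase")
        if self.voxel_count < 1:
            raise EmptyVOI("TAC voxel_count must be >= 1")

    def __len__(self) -> int:
        return len(self.activity)


# ---------------------------------------------------------------------------
# SimpleITK bridge (internal)
# ---------------------------------------------------------------------------

def _to_sitk(arr_xyz: np.ndarray, geom: ImageGeometry) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(arr_xyz.T.astype(np.float64)))
    img.SetSpacing([float(s) for s in geom.spacing])
    img.SetOrigin([float(o) for o in geom.origin])
    img.SetDirection([float(v) for v in geom.direction.ravel()])
    return img


def _from_sitk(img: sitk.Image) -> np.ndarray:
    return np.asarray(sitk.GetArrayFromImage(img)).T


def _reference_image(geom: ImageGeometry) -> sitk.Image:
    img = sitk.Image(list(geom.dims), sitk.sitkFloat64)
    img.SetSpacing([float(s) for s in geom.spacing])
    img.SetOrigin([float(o) for o in geom.origin])
    img.SetDirection([float(v) for v in geom.direction.ravel()])
    return img


_INTERPOLATORS = {"nearest": sitk.sitkNearestNeighbor, "linear": sitk.sitkLinear}


def _resample_array(
    arr: np.ndarray,
    geom: ImageGeometry,
    target: ImageGeometry,
    transform: RigidTransform,
    interpolation: str,
    fill: float,
) -> np.ndarray:
    if interpolation not in _INTERPOLATORS:
        raise ConfigError(f"unknown interpolation '{interpolation}'")
    out = sitk.Resample(
        _to_sitk(arr, geom),
        _reference_image(target),
        transform.to_sitk(),
        _INTERPOLATORS[interpolation],
        float(fill),
        sitk.sitkFloat64,
    )
    return _from_sitk(out)


def resample_to_grid(
    image: "DynamicPETSeries | CTVolume | ScalarVolume",
    target: ImageGeometry,
    transform: RigidTransform | None = None,
    interpolation: str = "linear",
):
    """Resample an image onto ``target``; ``transform`` maps target physical
    space into the source space (identity when omitted).

    Out-of-field voxels are filled with 0 kBq/cc for PET and -1000 HU for CT.
    """
    transform = transform or RigidTransform.identity()
    if isinstance(image, DynamicPETSeries):
        frames = [
            _resample_array(image.voxels[..., f], image.geometry, target, transform,
                            interpolation, 0.0)
            for f in range(image.n_frames)
        ]
        vox = np.stack(frames, axis=-1).astype(image.voxels.dtype, copy=False)
        return DynamicPETSeries(vox, target, image.schedule, image.decay_corrected)
    if isinstance(image, CTVolume):
        vox = _resample_array(image.voxels, image.geometry, target, transform,
                              interpolation, -1000.0)
        return CTVolume(np.clip(vox, HU_MIN, HU_MAX).astype(image.voxels.dtype, copy=False),
                        target)
    if isinstance(image, ScalarVolume):
        vox = _resample_array(image.voxels, image.geometry, target, transform,
                              interpolation, 0.0)
        return ScalarVolume(vox.astype(image.voxels.dtype, copy=False), target)
    raise ConfigError(f"cannot resample object of type {type(image).__name__}")


def time_average(series: DynamicPETSeries, frames: Sequence[int] | None = None,
                 weight_by_duration: bool = True) -> ScalarVolume:
    """Duration-weighted mean over (a subset of) frames, as a static volume."""
    idx = np.arange(series.n_frames) if frames is None else np.asarray(frames, dtype=int)
    w = series.schedule.durations_s[idx] if weight_by_duration else np.ones(len(idx))
    w = w / w.sum()
    avg = np.tensordot(series.voxels[..., idx], w, axes=([3], [0]))
    return ScalarVolume(avg, series.geometry)


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def _load_nifti(path) -> tuple[np.ndarray, ImageGeometry]:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    try:
        geom = ImageGeometry.from_affine(img.affine, data.shape[:3])
    except GeometryError:
        raise
    return data, geom


def _save_nifti(arr: np.ndarray, geom: ImageGeometry, path) -> None:
    img = nib.Nifti1Image(arr, geom.affine)
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))


def read_dynamic_pet(volume_path, timing_path) -> DynamicPETSeries:
    """Read a 4D NIfTI plus its JSON timing sidecar into a DynamicPETSeries.

    The sidecar holds ``{"FrameTimesStartEnd": [[start_s, end_s], ...],
    "DecayCorrected": true}`` (decay correction defaults to true).
    """
    data, geom = _load_nifti(volume_path)
    if data.ndim != 4:
        raise NotDynamic(f"{volume_path}: expected 4D, got {data.ndim}D")
    try:
        with open(timing_path) as fh:
            sidecar = json.load(fh)
    except FileNotFoundError:
        raise FrameTimingMismatch(f"timing sidecar not found: {timing_path}")
    if TIMING_KEY not in sidecar:
        raise FrameTimingMismatch(f"{timing_path}: missing key '{TIMING_KEY}'")
    frames = [tuple(pair) for pair in sidecar[TIMING_KEY]]
    if len(frames) != data.shape[3]:
        raise FrameTimingMismatch(
            f"{data.shape[3]} frames in volume vs {len(frames)} timing rows"
        )
    schedule = FrameSchedule(tuple(frames))
    return DynamicPETSeries(np.asarray(data, dtype=np.float32), geom, schedule,
                            bool(sidecar.get(DECAY_KEY, True)))


def write_dynamic_pet(series: DynamicPETSeries, volume_path, timing_path) -> None:
    _save_nifti(series.voxels.astype(np.float32), series.geometry, volume_path)
    sidecar = {
        TIMING_KEY: [[float(a), float(b)] for a, b in series.schedule.frames],
        DECAY_KEY: bool(series.decay_corrected),
        "Units": "kBq/cc",
    }
    with open(timing_path, "w") as fh:
        json.dump(sidecar, fh, indent=1)


def read_ct(volume_path) -> CTVolume:
    data, geom = _load_nifti(volume_path)
    if data.ndim == 4:
        raise NotStatic(f"{volume_path}: expected 3D CT, got 4D")
    return CTVolume(np.asarray(data, dtype=np.float32), geom)


def write_ct(ct: CTVolume, volume_path) -> None:
    _save_nifti(ct.voxels.astype(np.float32), ct.geometry, volume_path)


def write_mask(voi: VOIMask, path) -> None:
    """Store a VOI as a 0/1 integer volume sharing the reference geometry."""
    _save_nifti(voi.mask.astype(np.uint8), voi.geometry, path)


def read_mask(path, label: str = "custom") -> VOIMask:
    data, geom = _load_nifti(path)
    if data.ndim != 3:
        raise NotStatic(f"{path}: expected 3D mask")
    return VOIMask(data > 0, geom, label=label)


def write_tac(tac: TimeActivityCurve, path) -> None:
    """Write a TAC as CSV with header (time_min, activity_kBq_cc, n_voxels)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["time_min", "activity_kBq_cc", "n_voxels"])
        for t, a in zip(tac.mid_times_min, tac.activity):
            w.writerow([repr(float(t)), repr(float(a)), tac.voxel_count])


def read_tac(path, label: str = "custom") -> TimeActivityCurve:
    times, acts, counts = [], [], []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            times.append(float(row["time_min"]))
            acts.append(float(row["activity_kBq_cc"]))
            counts.append(int(row["n_voxels"]))
    if not times:
        raise EmptyVOI(f"{path}: TAC file has no data rows")
    return TimeActivityCurve(np.array(times), np.array(acts), counts[0], label=label)
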