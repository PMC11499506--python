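"""Shared fixtures: phantoms and expensive pipeline runs built once per session."""

from __future__ import annotations

import numpy as np
import pytest

from petglu.fusion import motion_correct
from petglu.imaging import FrameSchedule, ImageGeometry, RigidTransform
from petglu.phantom import (
    PhantomSpec,
    RegionSpec,
    apply_known_motion,
    default_phantom_spec,
    make_ct_phantom,
    make_dynamic_pet_phantom,
)

#: Reduced 16-frame schedule used for motion experiments (35 min total).
SHORT_SCHEDULE = FrameSchedule.from_durations((20.0,) * 6 + (60.0,) * 4 + (300.0,) * 6)


def coarse_spec(**overrides) -> PhantomSpec:
    """Default thorax layout on a coarse 32x32x16 grid (same 256 mm FOV)."""
    geometry = ImageGeometry((32, 32, 16), (8.0, 8.0, 8.0))
    return default_phantom_spec(geometry=geometry, **overrides)


def tube_ct_spec() -> PhantomSpec:
    """Vertical vessel tube (radius 16 mm = 8 voxels) in soft background."""
    g = ImageGeometry((48, 48, 40), (2.0, 2.0, 2.0))
    regions = (
        RegionSpec("background", "ellcyl", hu=20.0, center=(48, 48, 40),
                   semi_axes=(46, 46, 1), kinetics=(0.1, 0.5, 0.01)),
        RegionSpec("vessel", "tube", hu=50.0, center=(48, 48, 40),
                   radius=16.0, blood=True, organ=True),
    )
    return default_phantom_spec(geometry=g, regions=regions)


def dice(a: np.ndarray, b: np.ndarray) -> float:
    return 2.0 * float((a & b).sum()) / float(a.sum() + b.sum())


@pytest.fixture(scope="session")
def default_spec():
    return default_phantom_spec()


@pytest.fixture(scope="session")
def ct_phantom(default_spec):
    return make_ct_phantom(default_spec)


@pytest.fixture(scope="session")
def pet_phantom(default_spec):
    return make_dynamic_pet_phantom(default_spec)


@pytest.fixture(scope="session")
def tube_phantom():
    return make_ct_phantom(tube_ct_spec())


@pytest.fixture(scope="session")
def motion_experiment():
    """Noiseless phantom with known integer-voxel motion on the early half of
    frames (the patient settles before the late, reference-defining frames),
    then motion-corrected.  Integer-voxel shifts make apply_known_motion an
    exact operation, so residual TAC error measures registration accuracy."""
    spec = default_phantom_spec(schedule=SHORT_SCHEDULE)
    pet, truth = make_dynamic_pet_phantom(spec)
    rng = np.random.default_rng(7)
    n = pet.n_frames
    spacing = np.asarray(spec.geometry.spacing)
    transforms = []
    for f in range(n):
        if f < n // 2:
            steps = rng.integers(-1, 2, 3)  # up to one voxel = 4 mm per axis
            transforms.append(RigidTransform(translation=tuple(steps * spacing)))
        else:
            transforms.append(RigidTransform.identity())
    moved = apply_known_motion(pet, transforms)
    corrected, report = motion_correct(moved)
    return {
        "spec": spec,
        "pet": pet,
        "truth": truth,
        "transforms": transforms,
        "moved": moved,
        "corrected": corrected,
        "report": report,
    }


@pytest.fixture(scope="session")
def quantify_run(tmp_path_factory):
    """One full CLI run (simulate -> quantify) on the default noiseless
    phantom, shared by the end-to-end tests."""
    import pandas as pd
    import yaml

    from petglu.cli import main

    root = tmp_path_factory.mktemp("pipeline")
    phantom_dir = root / "phantom"
    out_dir = root / "out"
    assert main(["simulate", "--out", str(phantom_dir), "--seed", "0"]) == 0
    config = {
        "paths": {
            "pet": str(phantom_dir / "pet.nii.gz"),
            "timing": str(phantom_dir / "pet_timing.json"),
            "ct": str(phantom_dir / "ct.nii.gz"),
            "output": str(out_dir),
        },
        "seeds": {
            "aorta": [160, 140, 62],
            "myocardium": [118, 136, 62],
            "left_ventricle": [96, 136, 62],
        },
        "voi": {"hu_window": [45, 65]},
        "kinetics": {"t_star_min": 10, "plasma_glucose_mg_dl": 100},
    }
    cfg_path = root / "quantify.yaml"
    cfg_path.write_text(yaml.safe_dump(config))
    assert main(["quantify", "--config", str(cfg_path)]) == 0
    return {
        "root": root,
        "phantom_dir": phantom_dir,
        "out_dir": out_dir,
        "config_path": cfg_path,
        "config": config,
        "results": pd.read_csv(out_dir / "results.csv").set_index("district"),
        "truth": pd.read_csv(phantom_dir / "truth.csv").set_index("district"),
    }
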