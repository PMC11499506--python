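"""Rigid motion correction of a dynamic series with known ground truth.

Applies known per-frame translations to the early frames of a phantom
acquisition (the simulated patient settles before the late frames), runs
frame-to-reference rigid registration, and reports how well the transforms
and the aorta time-activity curve are restored.
"""

import numpy as np

from petglu.fusion import motion_correct
from petglu.imaging import FrameSchedule, RigidTransform
from petglu.kinetics import compute_tac
from petglu.phantom import apply_known_motion, default_phantom_spec, make_dynamic_pet_phantom

schedule = FrameSchedule.from_durations((20.0,) * 6 + (60.0,) * 4 + (300.0,) * 6)
spec = default_phantom_spec(schedule=schedule)
pet, truth = make_dynamic_pet_phantom(spec)

rng = np.random.default_rng(7)
spacing = np.asarray(spec.geometry.spacing)
n = pet.n_frames
transforms = [
    RigidTransform(translation=tuple(rng.integers(-1, 2, 3) * spacing))
    if f < n // 2 else RigidTransform.identity()
    for f in range(n)
]
moved = apply_known_motion(pet, transforms)
corrected, report = motion_correct(moved)

print(f"reference: {report.reference}, metric: {report.metric}")
for f, (rec, app) in enumerate(zip(report.transforms, transforms)):
    err = np.linalg.norm(rec._offset() - app.inverse()._offset())
    print(f"frame {f:2d}: applied {tuple(app.translation)} -> "
          f"residual {err:.2f} mm")

voi = truth.mask_voi("aorta")
ref = compute_tac(pet, voi).activity
cor = compute_tac(corrected, voi).activity
raw = compute_tac(moved, voi).activity
print(f"aorta TAC error vs never-moved: corrected "
      f"{100 * np.max(np.abs(cor - ref) / ref):.2f}% , uncorrected "
      f"{100 * np.max(np.abs(raw - ref) / ref):.2f}%")
print("Residuals should be well under half a voxel (2 mm) and the corrected")
print("TAC within 2% of the never-moved curve at every frame.")
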