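"""Patlak graphical analysis on analytic curves.

Builds a plasma input function and the two-tissue-compartment tissue
response with known rate constants, then recovers the net influx constant
Ki = K1*k3/(k2+k3) from the slope of the Patlak plot and converts it to a
metabolic rate of glucose.
"""

import numpy as np

from petglu import FrameSchedule, TimeActivityCurve
from petglu.kinetics import compute_mrglu, fit_patlak, patlak_transform
from petglu.phantom import (
    InputFunctionParams,
    default_phantom_spec,
    net_influx_ki,
    region_frame_curves,
)

K1, K2, K3 = 0.6, 1.2, 0.1  # 1/min

spec = default_phantom_spec()
curves, cp = region_frame_curves(spec)
t = spec.schedule.mid_times_min

tissue = TimeActivityCurve(t, curves["myocardium"], voxel_count=1, label="myocardium")
blood = TimeActivityCurve(t, cp, voxel_count=1, label="input")

points = patlak_transform(tissue, blood)
fit = fit_patlak(points, t_star_min=10.0)
result = compute_mrglu(fit, plasma_glucose_mg_dl=100.0, lumped_constant=1.0,
                       district="myocardium")

ki_true = net_influx_ki(K1, K2, K3)
print(f"true Ki         : {ki_true:.6f} mL/min/mL")
print(f"Patlak slope Ki : {fit.Ki:.6f} mL/min/mL  (r^2 = {fit.r_squared:.6f})")
print(f"intercept (V)   : {fit.intercept:.4f}")
print(f"MRGlu           : {result.value:.3f} umol/min/100g at 100 mg/dL, LC = 1")
print("The slope should match K1*k3/(k2+k3) to well under 5%; the intercept")
print("approximates the apparent distribution volume of the free tracer.")
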