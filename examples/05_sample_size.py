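"""Fit an inverse-power-law learning curve and invert it.

Uses synthetic accuracy observations at 12 training sizes, fits
y = (1 - a) - b*x^c by Levenberg-Marquardt, and asks how many training
subjects a target accuracy would require.
"""

import numpy as np

from marrowtex.learncurve import (
    CurvePoint,
    evaluate_curve,
    fit_inverse_power,
    prediction_bounds,
    required_sample_size,
)

rng = np.random.default_rng(3)
a_true, b_true, c_true = 0.12, 1.0, -0.45
sizes = (10, 20, 40, 60, 80, 100, 120, 140, 180, 240, 300, 360)
points = [
    CurvePoint(x=float(x),
               y=float((1 - a_true) - b_true * x**c_true + rng.normal(0, 0.01)))
    for x in sizes
]

fit, gof = fit_inverse_power(points)
print(f"fitted a={fit.a:.4f} b={fit.b:.4f} c={fit.c:.4f} "
      f"(true {a_true}, {b_true}, {c_true})")
print(f"SSE={gof.SSE:.2e}  RMSE={gof.RMSE:.4f}  asymptote={fit.asymptote:.3f}")

target = 0.85
need = required_sample_size(fit, target)
print(f"\ntraining size required for {target:.0%} accuracy: {need}")
print(f"curve at that size: {evaluate_curve(fit, need):.4f}")

yhat, lo, hi = prediction_bounds(fit, [need])
print(f"95% prediction bounds there: [{lo[0]:.4f}, {hi[0]:.4f}]")
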