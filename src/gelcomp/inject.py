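"""Injectability: linear modulus-to-force calibration and classification.

Syringe injection force correlates positively (and, as a first
approximation, linearly) with the plateau modulus of the loaded gel.
Calibrating that line on a few measured (G_p, force) pairs lets the
forward competitive-inhibition chain predict whether a formulation is
hand-injectable, conventionally meaning a plunger force at or below
38 N.  The comparison is inclusive: exactly 38 N is a comfort bound,
not a hard failure, and borderline cases are flagged in the report.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import linregress

from .errors import ValidationError

__all__ = ["ForceCalibration", "calibrate", "predict_force", "classify",
           "HAND_INJECTABLE_THRESHOLD_N"]

HAND_INJECTABLE_THRESHOLD_N = 38.0


@dataclass(frozen=True)
class ForceCalibration:
    """Ordinary least-squares line force = slope * G_p + intercept."""

    slope: float        # N/Pa
    intercept: float    # N
    threshold: float = HAND_INJECTABLE_THRESHOLD_N
    r_squared: float = float("nan")
    residuals: tuple[float, ...] = ()


def calibrate(points: Sequence[tuple[float, float]],
              threshold: float = HAND_INJECTABLE_THRESHOLD_N,
              ) -> ForceCalibration:
    """Fit the force-vs-modulus line on (G_p [Pa], force [N]) pairs."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise ValidationError("need >= 2 (modulus, force) pairs")
    g, force = pts[:, 0], pts[:, 1]
    if np.unique(g).size < 2:
        raise ValidationError("need >= 2 distinct modulus values to calibrate")
    if pts.shape[0] == 2:
        slope = (force[1] - force[0]) / (g[1] - g[0])
        intercept = force[0] - slope * g[0]
        r2 = 1.0
    else:
        fit = linregress(g, force)
        slope, intercept = float(fit.slope), float(fit.intercept)
        r2 = float(fit.rvalue ** 2)
    resid = force - (slope * g + intercept)
    return ForceCalibration(slope=slope, intercept=intercept,
                            threshold=threshold, r_squared=r2,
                            residuals=tuple(resid.tolist()))


def predict_force(calibration: ForceCalibration, g_p: float) -> float:
    """Predicted injection force (N) for a plateau modulus (Pa)."""
    if g_p < 0:
        raise ValidationError("g_p must be >= 0")
    return calibration.slope * g_p + calibration.intercept


def classify(force: float, calibration: ForceCalibration) -> str:
    """'hand_injectable' iff force <= threshold (inclusive)."""
    return ("hand_injectable" if force <= calibration.threshold
            else "not_injectable")
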