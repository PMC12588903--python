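"""Loewe equivalent-dose ("One-belt, One-line") combination analysis.

Two drugs T and E with monotone dose-inhibition curves are combined along a
ray of dose pairs.  For each pair the expected additive effect is computed
from both drugs' perspectives by equivalent-dose conversion:

    f_T = curveT(doseT + equivT(doseE))     (E converted into T units)
    g_E = curveE(doseE + equivE(doseT))     (T converted into E units)

The pointwise interval between f_T and g_E is the additive "belt"; the
observed combination dose-effect curve is the "line".  Dose-based combination
indices CI_d1 = Y_obs / f_T and CI_d2 = Y_obs / g_E quantify the interaction:
both above 1 → synergistic, both below 1 → antagonistic, otherwise additive.

Curves here are *percent-inhibition* Hill curves (increasing in dose):

    E(d) = floor + (ceiling - floor) / (1 + (ic50 / d) ** slope)

with floor/ceiling on the 0-100 percent scale; ``HillParams(0, 100, ic50, h)``
is the full-range curve.  ``effect_curve_from_viability`` converts a 0..1
viability parameterization.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
import pandas as pd

from .dose_response import HillParams

__all__ = [
    "CombinationRay",
    "AdditivePrediction",
    "CombinationIndexResult",
    "hill_effect",
    "invert_hill_effect",
    "effect_curve_from_viability",
    "equivalent_dose",
    "predict_additive",
    "combination_index",
    "judge_interaction",
    "analyze_ray",
    "round_half_up",
]

#: CI values within this distance of 1 are treated as exactly additive when
#: judging interactions (floating-point guard; Table-style data sit >= 1e-3 away).
CI_TIE_TOL = 1e-9


@dataclass
class CombinationRay:
    """A ray of paired doses with observed percent-inhibition effects."""

    dose_t: np.ndarray
    dose_e: np.ndarray
    observed_effect: np.ndarray
    curve_t: HillParams
    curve_e: HillParams

    def __post_init__(self) -> None:
        self.dose_t = np.asarray(self.dose_t, dtype=float)
        self.dose_e = np.asarray(self.dose_e, dtype=float)
        self.observed_effect = np.asarray(self.observed_effect, dtype=float)
        if not (self.dose_t.size == self.dose_e.size == self.observed_effect.size):
            raise ValueError("dose and effect columns must have equal length")
        if np.any(self.dose_t <= 0) or np.any(self.dose_e <= 0):
            raise ValueError("doses must be positive")
        if np.any((self.observed_effect < 0) | (self.observed_effect > 100)):
            raise ValueError("observed effects must lie in [0, 100] percent")


@dataclass(frozen=True)
class AdditivePrediction:
    f_t: float
    g_e: float
    saturated: bool = False

    @property
    def belt(self) -> tuple[float, float]:
        return (min(self.f_t, self.g_e), max(self.f_t, self.g_e))


@dataclass(frozen=True)
class CombinationIndexResult:
    ci_d1: float
    ci_d2: float
    judgment: str


def hill_effect(curve: HillParams, dose) -> np.ndarray | float:
    """Evaluate an increasing percent-inhibition Hill curve (dose 0 → floor)."""
    d = np.asarray(dose, dtype=float)
    with np.errstate(divide="ignore"):
        ratio = np.where(d > 0, (curve.ic50 / d) ** curve.slope, np.inf)
    e = curve.floor + (curve.ceiling - curve.floor) / (1.0 + ratio)
    return float(e) if e.ndim == 0 else e


def invert_hill_effect(curve: HillParams, effect: float) -> float:
    """Dose producing ``effect`` on the curve; floor → 0, ≥ ceiling → inf."""
    if curve.slope <= 0:
        raise ValueError("curve not invertible: slope must be positive")
    if effect <= curve.floor:
        return 0.0
    if effect >= curve.ceiling:
        return np.inf
    frac = (effect - curve.floor) / (curve.ceiling - curve.floor)
    return float(curve.ic50 * (frac / (1.0 - frac)) ** (1.0 / curve.slope))


def effect_curve_from_viability(v: HillParams) -> HillParams:
    """Mirror a 0..1 viability curve into a 0-100 percent-inhibition curve."""
    return HillParams(
        floor=100.0 * (1.0 - v.ceiling),
        ceiling=100.0 * (1.0 - v.floor),
        ic50=v.ic50,
        slope=v.slope,
    )


def equivalent_dose(curve_target: HillParams, curve_other: HillParams, dose_other: float) -> float:
    """Convert a dose of the other drug into the iso-effective target-drug dose.

    Returns ``inf`` when the other drug's effect exceeds the target curve's
    ceiling (no finite target dose reaches it).
    """
    if dose_other < 0:
        raise ValueError("dose_other must be non-negative")
    if dose_other == 0:
        return 0.0
    effect = hill_effect(curve_other, dose_other)
    return invert_hill_effect(curve_target, effect)


def predict_additive(ray: CombinationRay) -> list[AdditivePrediction]:
    """Expected additive effect of each pair from both drugs' perspectives.

    When an equivalent dose is infinite the prediction saturates at that
    curve's ceiling and is flagged.
    """
    out: list[AdditivePrediction] = []
    for dt, de in zip(ray.dose_t, ray.dose_e):
        eq_t = equivalent_dose(ray.curve_t, ray.curve_e, de)
        eq_e = equivalent_dose(ray.curve_e, ray.curve_t, dt)
        saturated = False
        if np.isinf(eq_t):
            f_t, saturated = ray.curve_t.ceiling, True
        else:
            f_t = float(hill_effect(ray.curve_t, dt + eq_t))
        if np.isinf(eq_e):
            g_e, saturated = ray.curve_e.ceiling, True
        else:
            g_e = float(hill_effect(ray.curve_e, de + eq_e))
        out.append(AdditivePrediction(f_t=f_t, g_e=g_e, saturated=saturated))
    return out


def combination_index(y_obs: float, f_t: float, g_e: float) -> CombinationIndexResult:
    """Dose-based combination indices CI_d1 = Y_obs/f_T and CI_d2 = Y_obs/g_E."""
    if y_obs < 0 or f_t < 0 or g_e < 0:
        raise ValueError("effects must be non-negative percent values")
    if f_t == 0 or g_e == 0:
        if y_obs == 0:
            ci1 = ci2 = 0.0
        else:
            raise ValueError("additive prediction is zero with nonzero observed effect")
    else:
        ci1 = y_obs / f_t
        ci2 = y_obs / g_e
    return CombinationIndexResult(ci_d1=ci1, ci_d2=ci2, judgment=judge_interaction(ci1, ci2))


def judge_interaction(ci_d1: float, ci_d2: float, mode: str = "row_pattern") -> str:
    """Classify the interaction from the CI pair.

    ``row_pattern`` (default): both indices above 1 → synergistic, both below
    1 → antagonistic, anything else (mixed, or within ``CI_TIE_TOL`` of 1) →
    additive.  ``strict`` applies the literal footnote-style rule (synergy
    both > 1; antagonism both < 1; addition both ≤ 1), in which mixed pairs
    fall back to additive as well — the two modes differ only for pairs with
    both indices at or below 1 where at least one equals 1.
    """
    if ci_d1 < 0 or ci_d2 < 0:
        raise ValueError("CI values must be non-negative")
    gt1 = (ci_d1 > 1.0 + CI_TIE_TOL, ci_d2 > 1.0 + CI_TIE_TOL)
    lt1 = (ci_d1 < 1.0 - CI_TIE_TOL, ci_d2 < 1.0 - CI_TIE_TOL)
    if all(gt1):
        return "synergistic"
    if mode == "strict":
        if all(lt1):
            return "antagonistic"
        if not any(gt1):
            return "additive"
        return "additive"
    if all(lt1):
        return "antagonistic"
    return "additive"


def round_half_up(x: float, ndigits: int) -> float:
    """Decimal half-up rounding, matching tabulated report formatting."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def analyze_ray(ray: CombinationRay) -> pd.DataFrame:
    """Per-pair additive predictions, CI pair and judgment, plus the belt.

    Effects are reported at 2 dp and CI at 4 dp (half-up); the unrounded CI
    drives the judgment.  Columns ``belt_low``/``belt_high`` give the additive
    band for plotting the one-belt, one-line comparison.
    """
    preds = predict_additive(ray)
    rows = []
    for dt, de, y, pred in zip(ray.dose_t, ray.dose_e, ray.observed_effect, preds):
        res = combination_index(float(y), pred.f_t, pred.g_e)
        lo, hi = pred.belt
        rows.append(
            {
                "dose_t": dt,
                "dose_e": de,
                "f_additive": round_half_up(pred.f_t, 2),
                "g_additive": round_half_up(pred.g_e, 2),
                "y_obs": round_half_up(float(y), 2),
                "ci_d1": round_half_up(res.ci_d1, 4),
                "ci_d2": round_half_up(res.ci_d2, 4),
                "judgment": res.judgment,
                "belt_low": lo,
                "belt_high": hi,
            }
        )
    return pd.DataFrame(rows)
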