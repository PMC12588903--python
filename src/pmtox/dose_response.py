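"""CCK-8 viability computation, Hill (4PL) dose-response fitting and toxicity tiers.

The viability curve is parameterized as

    v(d) = floor + (ceiling - floor) / (1 + (d / ic50) ** slope)

which decreases monotonically in dose for slope > 0.  ``ic50`` is the dose at
which viability sits halfway between the two asymptotes.  Percent-inhibition
("effect") curves used by :mod:`pmtox.combination` are the mirror image,
``effect(d) = 100 * (1 - v(d))`` for a 0..1 viability curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "HillParams",
    "PlateReadings",
    "DoseResponseFit",
    "viability",
    "hill_viability",
    "fit_hill",
    "classify_toxicity_tier",
    "read_plate_csv",
]


@dataclass(frozen=True)
class HillParams:
    """Four-parameter logistic curve parameters.

    ``floor``/``ceiling`` are the lower/upper viability asymptotes (fractions
    for viability curves, percent for inhibition-effect curves), ``ic50`` the
    midpoint dose and ``slope`` the positive Hill coefficient.
    """

    floor: float = 0.0
    ceiling: float = 1.0
    ic50: float = 1.0
    slope: float = 1.0

    def __post_init__(self) -> None:
        if not self.ceiling > self.floor:
            raise ValueError("ceiling must exceed floor")
        if not self.ic50 > 0:
            raise ValueError("ic50 must be positive")
        if not self.slope > 0:
            raise ValueError("slope must be positive")


@dataclass
class PlateReadings:
    """Plate-style absorbance rows: one (dose, dosing, blank, control) per well."""

    dose: np.ndarray
    absorbance_dosing: np.ndarray
    absorbance_blank: np.ndarray
    absorbance_control: np.ndarray
    replicate: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dose = np.asarray(self.dose, dtype=float)
        self.absorbance_dosing = np.asarray(self.absorbance_dosing, dtype=float)
        self.absorbance_blank = np.asarray(self.absorbance_blank, dtype=float)
        self.absorbance_control = np.asarray(self.absorbance_control, dtype=float)
        n = self.dose.size
        for arr in (self.absorbance_dosing, self.absorbance_blank, self.absorbance_control):
            if arr.size != n:
                raise ValueError("all plate columns must have equal length")
        if np.any(self.absorbance_control <= self.absorbance_blank):
            raise ValueError("control absorbance must exceed blank absorbance")

    def viabilities(self) -> np.ndarray:
        return viability(self.absorbance_dosing, self.absorbance_blank, self.absorbance_control)


@dataclass
class DoseResponseFit:
    params: HillParams
    residual_sse: float
    converged: bool
    n_points: int
    ic50_extrapolated: bool = False
    message: str = ""


def viability(dosing, blank, control):
    """CCK-8 viability fraction ``(dosing - blank) / (control - blank)``.

    Invariant under common gain/offset rescaling of the three absorbances.
    May exceed 1 slightly for proliferating wells; values are not clipped.
    """
    dosing = np.asarray(dosing, dtype=float)
    blank = np.asarray(blank, dtype=float)
    control = np.asarray(control, dtype=float)
    if np.any(control <= blank):
        raise ValueError("control absorbance must exceed blank absorbance")
    out = (dosing - blank) / (control - blank)
    return float(out) if out.ndim == 0 else out


def hill_viability(params: HillParams, dose) -> np.ndarray | float:
    """Evaluate the decreasing viability curve at ``dose`` (dose 0 allowed)."""
    d = np.asarray(dose, dtype=float)
    with np.errstate(divide="ignore"):
        ratio = np.where(d > 0, (d / params.ic50) ** params.slope, 0.0)
    v = params.floor + (params.ceiling - params.floor) / (1.0 + ratio)
    return float(v) if v.ndim == 0 else v


def _prepare_points(points) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
    """Collapse input to (dose, mean viability, optional weights)."""
    if isinstance(points, PlateReadings):
        doses, viab = points.dose, points.viabilities()
    else:
        doses, viab = points
        doses = np.asarray(doses, dtype=float)
        viab = np.asarray(viab, dtype=float)
    if np.any(doses <= 0):
        raise ValueError("doses must be positive")
    # average replicates per distinct dose; weight by 1/var when available
    uniq = np.unique(doses)
    means = np.empty(uniq.size)
    weights = np.ones(uniq.size)
    any_var = False
    for i, d in enumerate(uniq):
        vals = viab[doses == d]
        means[i] = vals.mean()
        if vals.size >= 2 and vals.var(ddof=1) > 0:
            weights[i] = 1.0 / vals.var(ddof=1)
            any_var = True
    return uniq, means, (weights if any_var else None)


def fit_hill(points, fix_floor_ceiling: bool = True) -> DoseResponseFit:
    """Least-squares Hill fit; deterministic multi-start on a log-spaced IC50 grid.

    With ``fix_floor_ceiling`` the asymptotes are pinned at 0 and 1 (sensible
    when the dosed range does not cover both plateaus); otherwise a free 4PL
    fit is attempted.  Non-convergence or a degenerate (flat) response is
    reported via ``converged=False`` rather than an exception.
    """
    doses, v, w = _prepare_points(points)
    n_min = 2 if fix_floor_ceiling else 4
    if doses.size < n_min:
        raise ValueError(f"need at least {n_min} distinct doses")
    sqrt_w = np.sqrt(w) if w is not None else np.ones_like(doses)

    if v.max() - v.min() < 0.05:
        # flat response: no identifiable midpoint in (or near) the dosed range
        return DoseResponseFit(
            params=HillParams(0.0, 1.0, float(np.median(doses)), 1.0),
            residual_sse=float(np.sum((v - v.mean()) ** 2)),
            converged=False,
            n_points=int(doses.size),
            message="response nearly constant over dosed range; IC50 unidentifiable",
        )

    log_d = np.log(doses)

    def _logistic(log_ic50, log_slope):
        z = np.clip(np.exp(log_slope) * (log_d - log_ic50), -700, 700)
        return 1.0 / (1.0 + np.exp(z))

    def residuals_fixed(theta):
        return sqrt_w * (_logistic(*theta) - v)

    def residuals_free(theta):
        log_ic50, log_slope, floor, ceiling = theta
        vv = floor + (ceiling - floor) * _logistic(log_ic50, log_slope)
        return sqrt_w * (vv - v)

    starts = np.log(np.geomspace(doses.min(), doses.max(), 7))
    best = None
    for s in starts:
        for log_slope0 in (np.log(0.5), 0.0, np.log(2.0)):
            if fix_floor_ceiling:
                res = optimize.least_squares(residuals_fixed, x0=[s, log_slope0], method="lm")
            else:
                res = optimize.least_squares(
                    residuals_free, x0=[s, log_slope0, float(v.min()), float(v.max())],
                    method="trf",
                    bounds=([-np.inf, -np.inf, -0.5, 0.0], [np.inf, np.inf, 1.0, 2.0]),
                )
            if best is None or res.cost < best.cost - 1e-15:
                best = res
    assert best is not None
    sse = float(2.0 * best.cost)
    if fix_floor_ceiling:
        log_ic50, log_slope = best.x
        floor, ceiling = 0.0, 1.0
    else:
        log_ic50, log_slope, floor, ceiling = best.x
    ic50 = float(np.exp(log_ic50))
    slope = float(np.exp(log_slope))
    ok = bool(best.success) and np.isfinite(sse) and ceiling > floor
    extrapolated = not (doses.min() <= ic50 <= doses.max())
    params = HillParams(float(floor), float(ceiling), ic50, slope) if ok else HillParams(
        0.0, 1.0, ic50 if ic50 > 0 else float(np.median(doses)), max(slope, 1e-6)
    )
    return DoseResponseFit(
        params=params,
        residual_sse=sse,
        converged=ok,
        n_points=int(doses.size),
        ic50_extrapolated=extrapolated,
        message="" if ok else "optimizer did not converge",
    )


def classify_toxicity_tier(ic50: float, low_cutoff: float = 450.0, high_cutoff: float = 390.0) -> str:
    """Three-tier hepatotoxicity class from an IC50 in µg/mL.

    IC50 > 450 → "low" toxicity, IC50 < 390 → "high", 390–450 inclusive → "medium".
    """
    if not ic50 > 0:
        raise ValueError("ic50 must be positive")
    if ic50 > low_cutoff:
        return "low"
    if ic50 < high_cutoff:
        return "high"
    return "medium"


def read_plate_csv(path) -> PlateReadings:
    """Read a plate CSV with columns dose, dosing, blank, control[, replicate]."""
    df = pd.read_csv(path)
    required = {"dose", "dosing", "blank", "control"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"plate CSV missing columns: {sorted(missing)}")
    rep = df["replicate"].to_numpy() if "replicate" in df.columns else None
    return PlateReadings(
        dose=df["dose"].to_numpy(),
        absorbance_dosing=df["dosing"].to_numpy(),
        absorbance_blank=df["blank"].to_numpy(),
        absorbance_control=df["control"].to_numpy(),
        replicate=rep,
    )
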