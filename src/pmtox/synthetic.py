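"""Synthetic study-shaped data: compound tables, viability plates, combination
rays and chromaticity readings.

The generator emulates the statistical structure the analysis pipeline
assumes: 61 batches in four latent composition groups (one unqualified),
stilbene glycosides dominating the profile with THSG carrying most of its
class total, Hill-shaped viability with group-tiered IC50s (low-toxicity
group above 450 µg/mL, high below 390, medium between), group-linked surface
colors (white safer, yellow-brown more toxic), and combination rays drawn
from an exact Loewe-additive surface, optionally potency-shifted to inject
synergy or antagonism.

Concentrations are drawn log-normal (positive, right-skewed; the CV sets the
log-scale sigma, and a CV of zero reproduces the group means exactly).  All
randomness flows from a single seed through per-stream generators so each
data kind can be regenerated independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .chromaticity import REGIONS, SURFACES, ChromaticityRecord
from .combination import CombinationRay, invert_hill_effect, hill_effect
from .compounds import CompoundTable
from .dose_response import HillParams, PlateReadings, hill_viability

__all__ = [
    "SyntheticConfig",
    "DEFAULT_COMPOUND_MEANS",
    "DEFAULT_HILL_BY_GROUP",
    "DEFAULT_CHROMA_BY_GROUP",
    "generate_compound_table",
    "generate_viability_plate",
    "generate_combination_ray",
    "generate_chromaticity",
    "loewe_additive_effect",
    "two_group_config",
]


class SyntheticConfigError(ValueError):
    """Inconsistent generator configuration."""


# --- default study conditions ------------------------------------------------

_ANTHRAQUINONES = [
    "emodin", "physcion", "physcion-8-O-glucoside", "trans-emodin-dianthrones",
    "EG", "emodin-8-O-(6'-methylmalonyl)-glucoside", "rhein",
    "emodin-6-O-glucoside", "1-methylemodin", "emodin-1-O-glucoside",
    "cis-emodin-dianthrones", "physcion-8-O-(6'-methylmalonyl)-glucoside",
]
_STILBENES = ["THSG", "cis-THSG", "feruloyl-THSG", "resveratrol", "polydatin"]
_FLAVONOIDS = ["catechin", "epicatechin", "rutin", "quercetin"]
_PHENOLS = [
    "gallic-acid", "p-hydroxybenzoic-acid", "torachrysone-8-O-glucoside",
    "protocatechuic-acid", "caffeic-acid",
]

COMPOUND_IDS = _ANTHRAQUINONES + _STILBENES + _FLAVONOIDS + _PHENOLS
COMPOUND_CLASS_MAP = (
    {c: "anthraquinone" for c in _ANTHRAQUINONES}
    | {c: "stilbene_glycoside" for c in _STILBENES}
    | {c: "flavonoid" for c in _FLAVONOIDS}
    | {c: "phenol" for c in _PHENOLS}
)


def _default_means() -> pd.DataFrame:
    """Per-group mean concentrations (mg/g dry weight).

    Group A is the sub-limit (THSG < 10 mg/g) unqualified group; THSG, EG,
    emodin and catechin carry the between-group differences; the remaining
    compounds share one mean across groups.
    """
    base = {
        "emodin": 0.4, "physcion": 0.5, "physcion-8-O-glucoside": 0.6,
        "trans-emodin-dianthrones": 0.5, "EG": 0.3,
        "emodin-8-O-(6'-methylmalonyl)-glucoside": 0.4, "rhein": 0.05,
        "emodin-6-O-glucoside": 0.05, "1-methylemodin": 0.05,
        "emodin-1-O-glucoside": 0.05, "cis-emodin-dianthrones": 0.05,
        "physcion-8-O-(6'-methylmalonyl)-glucoside": 0.05,
        "THSG": 12.5, "cis-THSG": 0.08, "feruloyl-THSG": 0.25,
        "resveratrol": 0.04, "polydatin": 0.18,
        "catechin": 0.5, "epicatechin": 0.3, "rutin": 0.05, "quercetin": 0.03,
        "gallic-acid": 0.3, "p-hydroxybenzoic-acid": 0.05,
        "torachrysone-8-O-glucoside": 0.15, "protocatechuic-acid": 0.05,
        "caffeic-acid": 0.03,
    }
    means = pd.DataFrame({g: base for g in "ABCD"}).T[COMPOUND_IDS]
    # each group carries a distinct overall composition profile (class-level
    # multipliers), so profiles are separable the way the four latent batch
    # groups are
    profile = {
        "A": {"anthraquinone": 0.5, "stilbene_glycoside": 0.8, "flavonoid": 0.9, "phenol": 1.2},
        "B": {"anthraquinone": 0.7, "stilbene_glycoside": 1.0, "flavonoid": 1.0, "phenol": 1.0},
        "C": {"anthraquinone": 1.6, "stilbene_glycoside": 1.8, "flavonoid": 0.7, "phenol": 0.6},
        "D": {"anthraquinone": 1.1, "stilbene_glycoside": 1.3, "flavonoid": 1.5, "phenol": 0.9},
    }
    for g in "ABCD":
        for c in COMPOUND_IDS:
            means.loc[g, c] = base[c] * profile[g][COMPOUND_CLASS_MAP[c]]
    means.loc["A", ["THSG", "EG", "emodin", "catechin"]] = [7.0, 0.5, 0.5, 0.5]
    means.loc["B", ["THSG", "EG", "emodin", "catechin"]] = [12.5, 0.3, 0.4, 0.5]
    means.loc["C", ["THSG", "EG", "emodin", "catechin"]] = [45.0, 3.0, 1.2, 0.6]
    means.loc["D", ["THSG", "EG", "emodin", "catechin"]] = [25.0, 1.5, 1.8, 1.2]
    return means


DEFAULT_COMPOUND_MEANS = _default_means()

#: viability Hill curves per group; IC50 tiers: low >450, medium 390-450, high <390
DEFAULT_HILL_BY_GROUP: dict[str, HillParams] = {
    "A": HillParams(0.0, 1.0, 540.0, 2.5),
    "B": HillParams(0.0, 1.0, 480.0, 2.5),
    "C": HillParams(0.0, 1.0, 370.0, 2.5),
    "D": HillParams(0.0, 1.0, 420.0, 2.5),
}

# white (B, safe) -> light-yellow (C, toxic) -> yellow-brown (D, medium):
# normalized B increases and normalized R decreases with IC50
_CHROMA_BASE = {
    "A": (185.0, 180.0, 175.0, 75.0, 3.0, 8.0),
    "B": (200.0, 192.0, 190.0, 80.0, 3.0, 9.0),
    "C": (225.0, 175.0, 100.0, 70.0, 8.0, 38.0),
    "D": (160.0, 144.0, 96.0, 55.0, 12.0, 30.0),
}
_REGION_OFFSET = {"cork": -10.0, "phloem": 5.0, "central_xylem": 10.0,
                  "heteromorphic_bundles": -5.0}


def _default_chroma() -> dict[str, dict[str, tuple[float, ...]]]:
    out: dict[str, dict[str, tuple[float, ...]]] = {}
    for g, (r, gg, b, l, a, bs) in _CHROMA_BASE.items():
        out[g] = {
            reg: (
                min(255.0, max(0.0, r + off)),
                min(255.0, max(0.0, gg + off)),
                min(255.0, max(0.0, b + off)),
                min(100.0, max(0.0, l + off / 4.0)),
                a, bs,
            )
            for reg, off in _REGION_OFFSET.items()
        }
    return out


DEFAULT_CHROMA_BY_GROUP = _default_chroma()

_ORIGINS = ("YN", "AH", "GD", "GZ", "SC")


@dataclass
class SyntheticConfig:
    """Study-condition parameters for the synthetic generators."""

    n_batches: int = 61
    group_names: tuple[str, ...] = ("A", "B", "C", "D")
    group_sizes: tuple[int, ...] = (5, 17, 21, 18)
    compound_means: pd.DataFrame = field(default_factory=_default_means)
    compound_cv: float = 0.2
    hill_params_by_group: dict[str, HillParams] = field(
        default_factory=lambda: dict(DEFAULT_HILL_BY_GROUP))
    chroma_means_by_group: dict[str, dict[str, tuple[float, ...]]] = field(
        default_factory=_default_chroma)
    noise_sd_viability: float = 0.05
    chroma_noise_sd: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.group_sizes) != len(self.group_names):
            raise SyntheticConfigError("group_sizes and group_names length mismatch")
        if any(s <= 0 for s in self.group_sizes):
            raise SyntheticConfigError("group sizes must be positive")
        if sum(self.group_sizes) != self.n_batches:
            raise SyntheticConfigError(
                f"group sizes sum to {sum(self.group_sizes)}, expected {self.n_batches}")
        if self.compound_cv < 0:
            raise SyntheticConfigError("compound_cv must be non-negative")
        if self.noise_sd_viability < 0 or self.chroma_noise_sd < 0:
            raise SyntheticConfigError("noise SDs must be non-negative")
        missing = [g for g in self.group_names if g not in self.compound_means.index]
        if missing:
            raise SyntheticConfigError(f"compound_means missing groups: {missing}")
        if (self.compound_means.to_numpy() < 0).any():
            raise SyntheticConfigError("compound means must be non-negative")

    def batch_groups(self) -> list[str]:
        out: list[str] = []
        for g, size in zip(self.group_names, self.group_sizes):
            out.extend([g] * size)
        return out


def _stream(seed: int, stream: int) -> np.random.Generator:
    # independent, reproducible sub-streams from one root seed
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stream,)))


def generate_compound_table(cfg: SyntheticConfig) -> CompoundTable:
    """Batch × compound matrix with log-normal scatter around group means."""
    rng = _stream(cfg.seed, 0)
    groups = cfg.batch_groups()
    compounds = list(cfg.compound_means.columns)
    rows = np.empty((cfg.n_batches, len(compounds)))
    cv = cfg.compound_cv
    sigma2 = np.log1p(cv**2)
    sigma = np.sqrt(sigma2)
    for i, g in enumerate(groups):
        means = cfg.compound_means.loc[g].to_numpy(dtype=float)
        if cv == 0:
            rows[i] = means
        else:
            # lognormal with mean exactly equal to the group mean
            mu = np.where(means > 0, np.log(np.where(means > 0, means, 1.0)) - sigma2 / 2, 0.0)
            draw = np.exp(rng.normal(mu, sigma))
            rows[i] = np.where(means > 0, draw, 0.0)
    batch_ids = [f"S{i + 1}" for i in range(cfg.n_batches)]
    origin = {b: _ORIGINS[i % len(_ORIGINS)] for i, b in enumerate(batch_ids)}
    return CompoundTable(
        batch_ids=batch_ids,
        compound_ids=compounds,
        concentrations=rows,
        compound_class={c: COMPOUND_CLASS_MAP.get(c, "phenol") for c in compounds},
        origin=origin,
        group=dict(zip(batch_ids, groups)),
    )


def generate_viability_plate(curve: HillParams, doses: Sequence[float],
                             noise_sd: float, seed: int,
                             n_replicates: int = 4,
                             control_absorbance: float = 1.5,
                             blank_absorbance: float = 0.1) -> PlateReadings:
    """Absorbance triplets whose derived viability is Hill(dose) plus noise.

    Noise is additive Gaussian on the viability scale, truncated at 0.
    """
    doses = np.asarray(doses, dtype=float)
    if np.any(doses <= 0):
        raise ValueError("doses must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    dose_col = np.repeat(doses, n_replicates)
    v = hill_viability(curve, dose_col)
    v = np.maximum(v + rng.normal(0.0, noise_sd, size=dose_col.size) if noise_sd > 0 else v, 0.0)
    span = control_absorbance - blank_absorbance
    return PlateReadings(
        dose=dose_col,
        absorbance_dosing=blank_absorbance + v * span,
        absorbance_blank=np.full(dose_col.size, blank_absorbance),
        absorbance_control=np.full(dose_col.size, control_absorbance),
        replicate=np.tile(np.arange(1, n_replicates + 1), doses.size),
    )


def loewe_additive_effect(curve_a: HillParams, curve_b: HillParams,
                          dose_a: float, dose_b: float) -> float:
    """Effect Y on the exact Loewe-additive surface: solves
    dose_a/D_A(Y) + dose_b/D_B(Y) = 1 for percent-inhibition curves.

    Saturates at the lower of the two ceilings when the combined dose exceeds
    the invertible range.
    """
    if dose_a < 0 or dose_b < 0:
        raise ValueError("doses must be non-negative")
    if dose_a == 0 and dose_b == 0:
        return max(curve_a.floor, curve_b.floor)
    if dose_b == 0:
        return float(hill_effect(curve_a, dose_a))
    if dose_a == 0:
        return float(hill_effect(curve_b, dose_b))
    lo = max(curve_a.floor, curve_b.floor)
    hi = min(curve_a.ceiling, curve_b.ceiling)

    def excess(y: float) -> float:
        da = invert_hill_effect(curve_a, y)
        db = invert_hill_effect(curve_b, y)
        return dose_a / da + dose_b / db - 1.0

    span = hi - lo
    y_lo, y_hi = lo + 1e-12 * span, hi - 1e-12 * span
    if excess(y_hi) > 0:
        return hi  # beyond invertible range: effect saturates
    # xtol tiny so that very small effects are still resolved to relative,
    # not absolute, precision (rtol is bounded below by ~4*eps)
    return float(optimize.brentq(excess, y_lo, y_hi, xtol=1e-300, rtol=8.9e-16))


def generate_combination_ray(curve_a: HillParams, curve_b: HillParams,
                             dose_pairs: Sequence[tuple[float, float]],
                             interaction: str = "loewe_additive",
                             potency_factor: float = 1.0,
                             noise_sd: float = 0.0, seed: int = 0) -> CombinationRay:
    """Combination ray with observed effects from a known interaction surface.

    ``loewe_additive`` draws Y_obs from the exact Loewe surface;
    ``potency_shift`` multiplies drug B's effective dose by ``potency_factor``
    before evaluating that surface (factor > 1 injects synergy, < 1
    antagonism).  Gaussian noise (percent scale) is added and clipped to
    [0, 100].
    """
    if interaction not in ("loewe_additive", "potency_shift"):
        raise ValueError(f"unknown interaction: {interaction!r}")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    pairs = [(float(a), float(b)) for a, b in dose_pairs]
    if any(a <= 0 or b <= 0 for a, b in pairs):
        raise ValueError("dose pairs must be positive")
    factor = potency_factor if interaction == "potency_shift" else 1.0
    effects = np.array(
        [loewe_additive_effect(curve_a, curve_b, a, factor * b) for a, b in pairs]
    )
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        effects = effects + rng.normal(0.0, noise_sd, size=effects.size)
    effects = np.clip(effects, 0.0, 100.0)
    return CombinationRay(
        dose_t=np.array([a for a, _ in pairs]),
        dose_e=np.array([b for _, b in pairs]),
        observed_effect=effects,
        curve_t=curve_a,
        curve_e=curve_b,
    )


def generate_chromaticity(cfg: SyntheticConfig) -> list[ChromaticityRecord]:
    """Per-batch 4 regions × 2 surfaces × 5 sites color readings.

    Gaussian noise (``cfg.chroma_noise_sd`` RGB units; quarter of that on
    L*/a*/b*) around the group's region means, clipped to channel ranges.
    """
    rng = _stream(cfg.seed, 1)
    groups = cfg.batch_groups()
    records: list[ChromaticityRecord] = []
    sd = cfg.chroma_noise_sd
    for i, g in enumerate(groups):
        batch = f"S{i + 1}"
        region_means = cfg.chroma_means_by_group[g]
        for region in REGIONS:
            r0, g0, b0, l0, a0, bs0 = region_means[region]
            for surface in SURFACES:
                for site in range(1, 6):
                    noise = rng.normal(0.0, 1.0, size=6) if sd > 0 else np.zeros(6)
                    records.append(
                        ChromaticityRecord(
                            batch_id=batch, region=region, surface=surface, site=site,
                            r=float(np.clip(r0 + sd * noise[0], 0, 255)),
                            g=float(np.clip(g0 + sd * noise[1], 0, 255)),
                            b=float(np.clip(b0 + sd * noise[2], 0, 255)),
                            l_star=float(np.clip(l0 + sd / 4 * noise[3], 0, 100)),
                            a_star=float(a0 + sd / 4 * noise[4]),
                            b_star=float(bs0 + sd / 4 * noise[5]),
                        )
                    )
    return records


def three_group_config(marker_compounds: Mapping[str, tuple[float, float, float]],
                       group_sizes: tuple[int, int, int] = (17, 21, 18),
                       compound_cv: float = 0.2, seed: int = 0) -> SyntheticConfig:
    """Three-tier configuration (safe / most toxic / intermediate) where only
    the given compounds differ between groups.

    ``marker_compounds`` maps compound id → (B, C, D) means.  Mirrors the
    study design in which markers are the compounds flagged in *both* the
    safe-vs-high-toxicity and safe-vs-medium-toxicity comparisons.
    """
    base = DEFAULT_COMPOUND_MEANS.loc["B"]
    means = pd.DataFrame([base, base, base], index=["B", "C", "D"])
    for comp, vals in marker_compounds.items():
        if comp not in means.columns:
            raise SyntheticConfigError(f"unknown compound: {comp}")
        means.loc["B", comp], means.loc["C", comp], means.loc["D", comp] = vals
    return SyntheticConfig(
        n_batches=sum(group_sizes),
        group_names=("B", "C", "D"),
        group_sizes=group_sizes,
        compound_means=means,
        compound_cv=compound_cv,
        hill_params_by_group={g: DEFAULT_HILL_BY_GROUP[g] for g in "BCD"},
        chroma_means_by_group={g: DEFAULT_CHROMA_BY_GROUP[g] for g in "BCD"},
        seed=seed,
    )


def two_group_config(marker_compounds: Mapping[str, tuple[float, float]],
                     group_sizes: tuple[int, int] = (17, 21),
                     compound_cv: float = 0.2, seed: int = 0) -> SyntheticConfig:
    """Two-group configuration where only the given compounds differ.

    ``marker_compounds`` maps compound id → (group-1 mean, group-2 mean);
    every other compound keeps the default group-B mean in both groups.  Used
    to test that the VIP ∧ FDR rule recovers exactly the designated markers.
    """
    base = DEFAULT_COMPOUND_MEANS.loc["B"]
    means = pd.DataFrame([base, base], index=["G1", "G2"])
    for comp, (m1, m2) in marker_compounds.items():
        if comp not in means.columns:
            raise SyntheticConfigError(f"unknown compound: {comp}")
        means.loc["G1", comp] = m1
        means.loc["G2", comp] = m2
    return SyntheticConfig(
        n_batches=sum(group_sizes),
        group_names=("G1", "G2"),
        group_sizes=group_sizes,
        compound_means=means,
        compound_cv=compound_cv,
        hill_params_by_group={"G1": DEFAULT_HILL_BY_GROUP["B"],
                              "G2": DEFAULT_HILL_BY_GROUP["C"]},
        chroma_means_by_group={"G1": DEFAULT_CHROMA_BY_GROUP["B"],
                               "G2": DEFAULT_CHROMA_BY_GROUP["C"]},
        seed=seed,
    )
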