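"""Chromaticity descriptors of decoction-piece surfaces and their link to
hepatotoxicity.

Each batch is measured at 4 anatomical regions (cork, phloem, central xylem,
heteromorphic vascular bundles) × 2 surfaces × 5 sites = 40 readings of
(R, G, B, L*, a*, b*).  Batch-level descriptors are the means over all 40
readings; from the means we derive the overall color parameter
E*ab = sqrt(L*² + a*² + b*²) and intensity-invariant normalized RGB fractions.
Normalized channels are regressed against batch IC50 values to test whether
surface color predicts toxicity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from skimage import color as skcolor

from . import chemometrics

__all__ = [
    "REGIONS",
    "SURFACES",
    "ChromaticityRecord",
    "BatchColorSummary",
    "aggregate_batch",
    "aggregate_batches",
    "e_ab",
    "normalize_rgb",
    "color_toxicity_regression",
    "color_hca",
    "extract_from_image",
    "records_to_frame",
    "records_from_frame",
]

REGIONS = ("cork", "phloem", "central_xylem", "heteromorphic_bundles")
SURFACES = ("front", "back")
N_RECORDS_PER_BATCH = len(REGIONS) * len(SURFACES) * 5


@dataclass(frozen=True)
class ChromaticityRecord:
    batch_id: str
    region: str
    surface: str
    site: int
    r: float
    g: float
    b: float
    l_star: float
    a_star: float
    b_star: float

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise ValueError(f"unknown region: {self.region!r}")
        if self.surface not in SURFACES:
            raise ValueError(f"unknown surface: {self.surface!r}")
        if not 1 <= self.site <= 5:
            raise ValueError("site must be 1..5")
        for name, v, lo, hi in (("r", self.r, 0, 255), ("g", self.g, 0, 255),
                                ("b", self.b, 0, 255), ("L*", self.l_star, 0, 100)):
            if not lo <= v <= hi:
                raise ValueError(f"{name} out of range [{lo}, {hi}]: {v}")


@dataclass(frozen=True)
class BatchColorSummary:
    batch_id: str
    mean_r: float
    mean_g: float
    mean_b: float
    mean_l: float
    mean_a: float
    mean_b_star: float
    e_ab: float
    norm_r: float
    norm_g: float
    norm_b: float
    complete: bool


def e_ab(l_star: float, a_star: float, b_star: float) -> float:
    """Overall color parameter sqrt(L*² + a*² + b*²)."""
    return float(np.sqrt(l_star**2 + a_star**2 + b_star**2))


def normalize_rgb(r: float, g: float, b: float) -> tuple[float, float, float]:
    """Intensity-invariant channel fractions summing to 1."""
    total = r + g + b
    if total <= 0:
        raise ValueError("r + g + b must be positive")
    return (r / total, g / total, b / total)


def aggregate_batch(records: Sequence[ChromaticityRecord]) -> BatchColorSummary:
    """Batch descriptor from its per-site readings.

    Channel means are taken over the raw readings; E*ab and normalized RGB are
    then derived from the batch means (aggregate-then-normalize order).  The
    summary is flagged incomplete unless all 40 (region, surface, site) cells
    are present exactly once.
    """
    if not records:
        raise ValueError("no records given")
    batch_ids = {rec.batch_id for rec in records}
    if len(batch_ids) != 1:
        raise ValueError(f"records span multiple batches: {sorted(batch_ids)}")
    cells = [(rec.region, rec.surface, rec.site) for rec in records]
    if len(set(cells)) != len(cells):
        dupes = sorted({c for c in cells if cells.count(c) > 1})
        raise ValueError(f"duplicate measurement cells: {dupes[:3]}")
    complete = len(cells) == N_RECORDS_PER_BATCH
    arr = np.array([[rec.r, rec.g, rec.b, rec.l_star, rec.a_star, rec.b_star]
                    for rec in records])
    mr, mg, mb, ml, ma, mbs = arr.mean(axis=0)
    nr, ng, nb = normalize_rgb(mr, mg, mb)
    return BatchColorSummary(
        batch_id=next(iter(batch_ids)),
        mean_r=float(mr), mean_g=float(mg), mean_b=float(mb),
        mean_l=float(ml), mean_a=float(ma), mean_b_star=float(mbs),
        e_ab=e_ab(ml, ma, mbs),
        norm_r=nr, norm_g=ng, norm_b=nb,
        complete=complete,
    )


def aggregate_batches(records: Iterable[ChromaticityRecord]) -> list[BatchColorSummary]:
    by_batch: dict[str, list[ChromaticityRecord]] = {}
    for rec in records:
        by_batch.setdefault(rec.batch_id, []).append(rec)
    return [aggregate_batch(v) for v in by_batch.values()]


def color_toxicity_regression(summaries: Sequence[BatchColorSummary],
                              ic50: Mapping[str, float]) -> pd.DataFrame:
    """OLS of IC50 on each normalized channel separately.

    Returns one row per channel with slope, intercept, r² and the two-sided
    p-value of the slope.  A positive normalized-B slope / negative
    normalized-R slope reproduces the white-is-safer direction.
    """
    usable = [s for s in summaries if s.batch_id in ic50]
    if len(usable) < 3:
        raise ValueError("need at least 3 batches with IC50 values")
    y = np.array([ic50[s.batch_id] for s in usable], dtype=float)
    rows = []
    for channel in ("norm_r", "norm_g", "norm_b"):
        x = np.array([getattr(s, channel) for s in usable])
        if np.ptp(x) == 0:
            raise ValueError(f"channel {channel} is constant; slope undefined")
        res = stats.linregress(x, y)
        rows.append(
            {"channel": channel, "slope": float(res.slope),
             "intercept": float(res.intercept), "r_squared": float(res.rvalue**2),
             "p_value": float(res.pvalue), "n": len(usable)}
        )
    return pd.DataFrame(rows)


def color_hca(summaries: Sequence[BatchColorSummary], k: int = 3,
              linkage: str = "ward", metric: str = "euclidean"):
    """Cluster batches on autoscaled color descriptors; returns (labels, tree)."""
    if len(summaries) < k:
        raise ValueError("need at least k batches")
    feats = np.array(
        [[s.norm_r, s.norm_g, s.norm_b, s.mean_l, s.mean_a, s.mean_b_star, s.e_ab]
         for s in summaries]
    )
    scaled = chemometrics.autoscale(feats, mode="unit_variance")
    return chemometrics.hca(scaled.values, linkage=linkage, metric=metric, k=k)


def extract_from_image(image, crop_box: tuple[int, int, int, int]) -> dict:
    """Mean RGB of a crop plus its CIELAB conversion (sRGB, D65, 2° observer).

    ``image`` is an (H, W, 3) uint8/float array or a PIL image; ``crop_box``
    is (left, upper, right, lower) in pixel coordinates.
    """
    arr = np.asarray(image)
    if arr.ndim != 3 or arr.shape[2] < 3:
        raise ValueError("image must be an (H, W, 3) array")
    left, upper, right, lower = crop_box
    h, w = arr.shape[:2]
    if not (0 <= left < right <= w and 0 <= upper < lower <= h):
        raise ValueError("crop box empty or out of bounds")
    crop = arr[upper:lower, left:right, :3].astype(float)
    mean_rgb = crop.reshape(-1, 3).mean(axis=0)
    lab = skcolor.rgb2lab((mean_rgb / 255.0).reshape(1, 1, 3)).reshape(3)
    return {
        "mean_rgb": tuple(float(v) for v in mean_rgb),
        "lab": tuple(float(v) for v in lab),
        "n_pixels": int(crop.shape[0] * crop.shape[1]),
    }


def records_to_frame(records: Sequence[ChromaticityRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"batch": r.batch_id, "region": r.region, "surface": r.surface, "site": r.site,
          "R": r.r, "G": r.g, "B": r.b, "L_star": r.l_star,
          "a_star": r.a_star, "b_star": r.b_star}
         for r in records]
    )


def records_from_frame(df: pd.DataFrame) -> list[ChromaticityRecord]:
    required = {"batch", "region", "surface", "site", "R", "G", "B",
                "L_star", "a_star", "b_star"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"chromaticity CSV missing columns: {sorted(missing)}")
    return [
        ChromaticityRecord(
            batch_id=str(row["batch"]), region=str(row["region"]),
            surface=str(row["surface"]), site=int(row["site"]),
            r=float(row["R"]), g=float(row["G"]), b=float(row["B"]),
            l_star=float(row["L_star"]), a_star=float(row["a_star"]),
            b_star=float(row["b_star"]),
        )
        for _, row in df.iterrows()
    ]
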