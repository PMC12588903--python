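import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pmtox import (
    ChromaticityRecord,
    SyntheticConfig,
    aggregate_batch,
    aggregate_batches,
    color_hca,
    color_toxicity_regression,
    e_ab,
    extract_from_image,
    generate_chromaticity,
    normalize_rgb,
)
from pmtox.chromaticity import REGIONS, SURFACES
from pmtox.synthetic import DEFAULT_HILL_BY_GROUP
from conftest import pair_counting_agreement


def _full_batch(batch="S1", rgb=(120.0, 60.0, 20.0), lab=(50.0, 10.0, 20.0)):
    return [
        ChromaticityRecord(batch, region, surface, site, *rgb, *lab)
        for region in REGIONS
        for surface in SURFACES
        for site in range(1, 6)
    ]


# ---------------------------------------------------------------------------
# elementary formulas


@pytest.mark.parametrize("lab, expected", [((3, 0, 4), 5.0), ((0, 0, 0), 0.0), ((77, 0, 0), 77.0)])
def test_e_ab_formula(lab, expected):
    assert e_ab(*lab) == pytest.approx(expected)


def test_e_ab_sign_insensitive():
    # depends on squares only: red and green casts of equal size coincide
    assert e_ab(50, 10, -20) == e_ab(50, -10, 20)


@pytest.mark.parametrize(
    "rgb, expected",
    [((100, 100, 100), (1 / 3, 1 / 3, 1 / 3)), ((255, 0, 0), (1, 0, 0)),
     ((120, 60, 20), (0.6, 0.3, 0.1))],
)
def test_normalize_rgb_examples(rgb, expected):
    assert normalize_rgb(*rgb) == pytest.approx(expected)


def test_normalize_rgb_zero_rejected():
    with pytest.raises(ValueError):
        normalize_rgb(0, 0, 0)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.tuples(*[st.floats(min_value=0.01, max_value=255)] * 3),
       st.floats(min_value=0.1, max_value=10))
def test_normalize_rgb_sums_to_one_and_scale_invariant(rgb, scale):
    out = normalize_rgb(*rgb)
    assert sum(out) == pytest.approx(1.0, abs=1e-10)
    scaled = normalize_rgb(*(scale * c for c in rgb))
    assert scaled == pytest.approx(out)


# ---------------------------------------------------------------------------
# aggregation


def test_aggregate_constant_records_reproduce_values():
    summary = aggregate_batch(_full_batch())
    assert summary.complete
    assert summary.mean_r == pytest.approx(120.0)
    assert summary.norm_r == pytest.approx(0.6)
    assert summary.e_ab == pytest.approx(e_ab(50.0, 10.0, 20.0))


def test_aggregate_incomplete_flag():
    records = _full_batch()[:-1]  # 39 of 40
    summary = aggregate_batch(records)
    assert not summary.complete


def test_aggregate_duplicate_cell_rejected():
    records = _full_batch()
    records.append(records[0])
    with pytest.raises(ValueError, match="duplicate"):
        aggregate_batch(records)


def test_aggregate_balanced_mean_of_two_levels():
    records = []
    for region in REGIONS:
        val = 100.0 if region in REGIONS[:2] else 200.0
        for surface in SURFACES:
            for site in range(1, 6):
                records.append(
                    ChromaticityRecord("S1", region, surface, site, val, val, val, 50, 0, 0))
    assert aggregate_batch(records).mean_r == pytest.approx(150.0)


def test_record_count_per_synthetic_batch_is_40():
    cfg = SyntheticConfig(seed=0)
    records = generate_chromaticity(cfg)
    assert len(records) == cfg.n_batches * 40
    per_batch = {}
    for r in records:
        per_batch[r.batch_id] = per_batch.get(r.batch_id, 0) + 1
    assert set(per_batch.values()) == {40}


# ---------------------------------------------------------------------------
# regression against IC50


def test_regression_exact_linear_relation():
    rng = np.random.default_rng(0)
    summaries = []
    ic50 = {}
    for i in range(12):
        r = float(rng.uniform(50, 200))
        b = float(rng.uniform(20, 150))
        g = 100.0
        recs = _full_batch(batch=f"S{i}", rgb=(r, g, b))
        s = aggregate_batch(recs)
        summaries.append(s)
        ic50[s.batch_id] = 100.0 + 1000.0 * s.norm_b
    reg = color_toxicity_regression(summaries, ic50).set_index("channel")
    assert reg.loc["norm_b", "slope"] == pytest.approx(1000.0, rel=1e-9)
    assert reg.loc["norm_b", "r_squared"] == pytest.approx(1.0, abs=1e-9)


def test_regression_null_channel_mostly_insignificant():
    rng = np.random.default_rng(1)
    insignificant = 0
    for rep in range(100):
        summaries = []
        ic50 = {}
        for i in range(100):
            rgb = tuple(rng.uniform(50, 200, size=3))
            s = aggregate_batch(_full_batch(batch=f"S{i}", rgb=rgb))
            summaries.append(s)
            ic50[s.batch_id] = float(rng.uniform(300, 500))
        reg = color_toxicity_regression(summaries, ic50).set_index("channel")
        insignificant += reg.loc["norm_b", "p_value"] > 0.05
    assert insignificant >= 90


def test_synthetic_groups_recover_sign_structure():
    """Safer (whiter) groups carry higher normalized B and lower normalized R,
    so the fitted slopes against IC50 must be positive and negative."""
    cfg = SyntheticConfig(seed=7)
    groups = dict(zip([f"S{i + 1}" for i in range(61)], cfg.batch_groups()))
    ic50 = {b: DEFAULT_HILL_BY_GROUP[g].ic50 for b, g in groups.items() if g in "BCD"}
    summaries = [s for s in aggregate_batches(generate_chromaticity(cfg))
                 if s.batch_id in ic50]
    reg = color_toxicity_regression(summaries, ic50).set_index("channel")
    assert reg.loc["norm_b", "slope"] > 0
    assert reg.loc["norm_r", "slope"] < 0


# ---------------------------------------------------------------------------
# color clustering


def test_color_hca_separates_synthetic_groups():
    cfg = SyntheticConfig(seed=2)
    groups = dict(zip([f"S{i + 1}" for i in range(61)], cfg.batch_groups()))
    summaries = [s for s in aggregate_batches(generate_chromaticity(cfg))
                 if groups[s.batch_id] in "BCD"]
    labels, _ = color_hca(summaries, k=3)
    truth = [groups[s.batch_id] for s in summaries]
    assert pair_counting_agreement(truth, labels) >= 0.9


def test_color_hca_k1_and_duplicates():
    s = aggregate_batch(_full_batch())
    s2 = aggregate_batch(_full_batch(batch="S2"))
    s3 = aggregate_batch(_full_batch(batch="S3", rgb=(30.0, 200.0, 90.0)))
    labels, _ = color_hca([s, s2, s3], k=2)
    assert labels[0] == labels[1]  # identical colors co-cluster
    labels1, _ = color_hca([s, s2, s3], k=1)
    assert len(set(labels1)) == 1


# ---------------------------------------------------------------------------
# image extraction


def test_extract_midgray_lab_reference():
    img = np.full((10, 10, 3), 128, dtype=np.uint8)
    out = extract_from_image(img, (0, 0, 10, 10))
    L, a, b = out["lab"]
    assert L == pytest.approx(53.6, abs=0.5)
    assert a == pytest.approx(0.0, abs=0.5)
    assert b == pytest.approx(0.0, abs=0.5)


def test_extract_white_point():
    img = np.full((4, 4, 3), 255, dtype=np.uint8)
    out = extract_from_image(img, (0, 0, 4, 4))
    L, a, b = out["lab"]
    assert L == pytest.approx(100.0, abs=1e-4)
    assert a == pytest.approx(0.0, abs=0.01)
    assert b == pytest.approx(0.0, abs=0.01)


def test_extract_single_pixel_and_bounds():
    img = np.zeros((5, 5, 3), dtype=np.uint8)
    img[2, 3] = (10, 20, 30)
    out = extract_from_image(img, (3, 2, 4, 3))
    assert out["mean_rgb"] == (10.0, 20.0, 30.0)
    assert out["n_pixels"] == 1
    with pytest.raises(ValueError):
        extract_from_image(img, (4, 4, 4, 5))  # empty crop
    with pytest.raises(ValueError):
        extract_from_image(img, (0, 0, 99, 2))
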