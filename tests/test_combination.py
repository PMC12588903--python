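import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pmtox import (
    CombinationRay,
    HillParams,
    analyze_ray,
    combination_index,
    equivalent_dose,
    generate_combination_ray,
    hill_effect,
    invert_hill_effect,
    judge_interaction,
    load_combination_table,
    loewe_additive_effect,
    predict_additive,
)
from pmtox.combination import effect_curve_from_viability, round_half_up

FULL_T = HillParams(0.0, 100.0, 417.0, 2.0)
FULL_E = HillParams(0.0, 100.0, 12.7, 2.0)


# ---------------------------------------------------------------------------
# equivalent-dose conversion


def test_equivalent_dose_self_identity():
    for d in (1.0, 50.0, 417.0, 900.0):
        assert equivalent_dose(FULL_T, FULL_T, d) == pytest.approx(d, rel=1e-9)


def test_equivalent_dose_iso_effect_at_ic50():
    # the other drug at its IC50 maps onto the target drug's IC50
    assert equivalent_dose(FULL_T, FULL_E, 12.7) == pytest.approx(417.0, rel=1e-9)
    assert equivalent_dose(FULL_E, FULL_T, 417.0) == pytest.approx(12.7, rel=1e-9)


def test_equivalent_dose_zero_and_saturation():
    assert equivalent_dose(FULL_T, FULL_E, 0.0) == 0.0
    low_ceiling = HillParams(0.0, 60.0, 417.0, 2.0)
    # the other drug reaches 80% which the target curve can never produce
    d80 = invert_hill_effect(FULL_E, 80.0)
    assert np.isinf(equivalent_dose(low_ceiling, FULL_E, d80))


def test_inversion_round_trip():
    curve = HillParams(5.0, 95.0, 123.0, 1.7)
    for e in (6.0, 30.0, 50.0, 90.0):
        assert hill_effect(curve, invert_hill_effect(curve, e)) == pytest.approx(e, abs=1e-6)


# ---------------------------------------------------------------------------
# additive predictions


def test_sham_pair_equals_curve_at_summed_dose():
    ray = CombinationRay([100.0], [100.0], [50.0], FULL_T, FULL_T)
    (pred,) = predict_additive(ray)
    expected = hill_effect(FULL_T, 200.0)
    assert pred.f_t == pytest.approx(expected, abs=1e-9)
    assert pred.g_e == pytest.approx(expected, abs=1e-9)


def test_additive_prediction_against_grid_inversion_oracle():
    """f and g must match a brute-force numerical inversion of the curves."""
    curve_t = HillParams(0.0, 100.0, 417.0, 1.8)
    curve_e = HillParams(0.0, 100.0, 12.7, 2.4)
    dt, de = 350.0, 12.5
    grid = np.geomspace(1e-4, 1e7, 2_000_001)

    def invert_numeric(curve, effect):
        vals = hill_effect(curve, grid)
        return float(np.interp(effect, vals, grid))

    eq_t = invert_numeric(curve_t, hill_effect(curve_e, de))
    eq_e = invert_numeric(curve_e, hill_effect(curve_t, dt))
    ray = CombinationRay([dt], [de], [50.0], curve_t, curve_e)
    (pred,) = predict_additive(ray)
    assert pred.f_t == pytest.approx(hill_effect(curve_t, dt + eq_t), abs=1e-4)
    assert pred.g_e == pytest.approx(hill_effect(curve_e, de + eq_e), abs=1e-4)
    lo, hi = pred.belt
    assert lo <= hi


# ---------------------------------------------------------------------------
# combination index + judgment


def test_ci_reproduces_published_row():
    res = combination_index(92.13, 56.91, 92.59)
    assert round_half_up(res.ci_d1, 4) == 1.6189
    assert round_half_up(res.ci_d2, 4) == 0.9950
    assert res.judgment == "additive"


def test_ci_zero_effect():
    res = combination_index(0.0, 8.03, 9.62)
    assert res.ci_d1 == 0.0 and res.ci_d2 == 0.0
    assert res.judgment == "antagonistic"


def test_ci_rejects_negative():
    with pytest.raises(ValueError):
        combination_index(-1.0, 10.0, 10.0)


@pytest.mark.parametrize(
    "ci1, ci2, expected",
    [
        (1.2862, 1.0494, "synergistic"),
        (1.6180, 0.8775, "additive"),
        (0.0, 0.0, "antagonistic"),
        (1.0, 1.0, "additive"),
        (1.0 + 1e-12, 1.0 - 1e-12, "additive"),  # within the tie band
    ],
)
def test_judgment_rule(ci1, ci2, expected):
    assert judge_interaction(ci1, ci2) == expected


def test_judgments_reproduce_all_published_rows():
    table = load_combination_table()
    for _, row in table.iterrows():
        assert judge_interaction(row["ci_d1_printed"], row["ci_d2_printed"]) == row["judgment"]


# ---------------------------------------------------------------------------
# ray analysis and the sham-consistency property


def test_loewe_ray_zero_noise_is_exactly_additive():
    pairs = [(50, 2), (150, 5), (300, 10), (450, 15)]
    ray = generate_combination_ray(FULL_T, FULL_E, pairs, noise_sd=0.0)
    out = analyze_ray(ray)
    assert np.allclose(out["ci_d1"], 1.0, atol=1e-6)
    assert np.allclose(out["ci_d2"], 1.0, atol=1e-6)
    assert (out["judgment"] == "additive").all()


def test_potency_shift_judged_synergistic_interior():
    pairs = [(250, 8), (350, 12.5), (450, 17.5)]
    ray = generate_combination_ray(FULL_T, FULL_E, pairs, interaction="potency_shift",
                                   potency_factor=2.0, noise_sd=0.0)
    out = analyze_ray(ray)
    assert (out["ci_d1"] > 1).all() and (out["ci_d2"] > 1).all()
    assert (out["judgment"] == "synergistic").all()


def test_ray_order_equivariance():
    pairs = [(100, 4), (250, 9), (400, 14)]
    ray_fwd = generate_combination_ray(FULL_T, FULL_E, pairs, noise_sd=0.0)
    ray_rev = generate_combination_ray(FULL_T, FULL_E, pairs[::-1], noise_sd=0.0)
    fwd = analyze_ray(ray_fwd).drop(columns="judgment")
    rev = analyze_ray(ray_rev).drop(columns="judgment")
    assert np.allclose(fwd.to_numpy(), rev.to_numpy()[::-1])


@settings(deadline=None, max_examples=100, derandomize=True)
@given(
    ic50=st.floats(min_value=1.0, max_value=1e4),
    slope=st.floats(min_value=0.3, max_value=6.0),
    total=st.floats(min_value=0.01, max_value=10.0),
    split=st.floats(min_value=0.01, max_value=0.99),
)
def test_sham_combination_ci_is_one(ic50, slope, total, split):
    """A drug combined with itself at any dose split is exactly additive."""
    curve = HillParams(0.0, 100.0, ic50, slope)
    d_total = total * ic50  # cover doses well below and above the midpoint
    d1, d2 = split * d_total, (1.0 - split) * d_total
    y = loewe_additive_effect(curve, curve, d1, d2)
    ray = CombinationRay([d1], [d2], [y], curve, curve)
    (pred,) = predict_additive(ray)
    res = combination_index(y, pred.f_t, pred.g_e)
    assert res.ci_d1 == pytest.approx(1.0, abs=1e-6)
    assert res.ci_d2 == pytest.approx(1.0, abs=1e-6)


def test_effect_curve_mirror():
    v = HillParams(0.1, 0.9, 417.0, 2.0)
    e = effect_curve_from_viability(v)
    assert e.floor == pytest.approx(10.0)
    assert e.ceiling == pytest.approx(90.0)
    d = 300.0
    from pmtox import hill_viability

    assert hill_effect(e, d) == pytest.approx(100.0 * (1.0 - hill_viability(v, d)))
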