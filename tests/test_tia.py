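"""Time-integrated activity: fit route, hybrid route, nuclide substitution."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate

import alphadose as ad

LN2 = math.log(2.0)


def test_single_term_closed_form():
    model = ad.MultiExponentialModel(terms=((10.0, LN2 / 24.0),), organ_label="x")
    r = ad.tia_from_fit(model)
    assert r.tia == pytest.approx(10.0 * 24.0 / LN2, rel=1e-12)
    assert r.method == "fit"


def test_fit_route_equals_auc(ac_blood_model):
    assert ad.tia_from_fit(ac_blood_model).tia == pytest.approx(
        ad.auc(ac_blood_model), rel=1e-14
    )


@given(
    st.lists(
        st.tuples(
            st.floats(min_value=0.1, max_value=40.0),
            st.floats(min_value=LN2 / 400.0, max_value=LN2 / 1.0),
        ),
        min_size=1,
        max_size=3,
    )
)
def test_fit_route_matches_quadrature_oracle(terms):
    model = ad.MultiExponentialModel(terms=tuple(terms), organ_label="x")
    numeric, _ = integrate.quad(lambda t: float(model.predict(t)), 0.0, np.inf, limit=500)
    assert ad.tia_from_fit(model).tia == pytest.approx(numeric, rel=1e-4)


def test_hybrid_converges_to_closed_form_under_dense_sampling():
    """0.1-h sampling over five half-lives reproduces the analytic integral to <1%."""
    t = np.arange(0.1, 5 * 24.0, 0.1)
    curve = ad.TimeActivityCurve("x", t, 10.0 * np.exp(-LN2 / 24.0 * t))
    r = ad.tia_hybrid(curve)
    assert r.tia == pytest.approx(10.0 * 24.0 / LN2, rel=0.01)


def test_hybrid_tail_is_terminal_concentration_over_loglinear_slope():
    """Two points halving over 72 h: tail = 5/(ln2/72) = 519.4 on top of the
    numerically integrated measured span."""
    curve = ad.TimeActivityCurve("x", np.array([72.0, 144.0]), np.array([10.0, 5.0]))
    r = ad.tia_hybrid(curve, leading_edge="none")
    assert r.components["tail"] == pytest.approx(5.0 * 72.0 / LN2, rel=1e-12)
    assert r.tia == pytest.approx(r.components["measured"] + r.components["tail"])
    assert r.tail_fraction == pytest.approx(r.components["tail"] / r.tia)


def test_hybrid_flat_tail_uses_physical_decay_fallback(ac225):
    curve = ad.TimeActivityCurve("liver", np.array([72.0, 144.0]), np.array([10.0, 10.0]))
    with pytest.raises(ValueError):
        ad.tia_hybrid(curve)  # no physical decay supplied
    r = ad.tia_hybrid(curve, physical_decay=ac225)
    assert "conservative-tail" in r.flags
    assert r.components["tail"] == pytest.approx(10.0 / ac225.decay_constant_per_h)


def test_hybrid_zero_terminal_concentration_flagged():
    curve = ad.TimeActivityCurve("x", np.array([24.0, 72.0]), np.array([4.0, 0.0]))
    r = ad.tia_hybrid(curve, leading_edge="none")
    assert "zero-terminal" in r.flags
    assert r.components["tail"] == 0.0


def test_hybrid_single_point_rejected():
    curve = ad.TimeActivityCurve("x", np.array([24.0]), np.array([4.0]))
    with pytest.raises(ValueError):
        ad.tia_hybrid(curve)


def test_hybrid_leading_edge_back_extrapolates_decaying_first_segment():
    """Blood-like first segment: the [0, t1] span integrates above c1*t1."""
    t = np.array([1.0, 6.0, 24.0, 72.0, 144.0])
    c = 30.0 * np.exp(-LN2 / 10.0 * t)
    r = ad.tia_hybrid(ad.TimeActivityCurve("blood", t, c))
    assert r.components["leading"] > c[0]
    lam = LN2 / 10.0
    assert r.components["leading"] == pytest.approx(
        c[0] * (np.exp(lam) - 1.0) / lam, rel=1e-12
    )


def test_hybrid_leading_edge_floors_rising_first_segment():
    """Uptake organs contribute a constant c1 before the first sample,
    never extrapolated extra activity."""
    t = np.array([1.0, 6.0, 24.0, 72.0, 144.0])
    c = np.array([2.0, 8.0, 15.0, 14.0, 10.0])
    r = ad.tia_hybrid(ad.TimeActivityCurve("spleen", t, c))
    assert r.components["leading"] == pytest.approx(2.0 * 1.0)


def test_substitution_with_zero_decay_is_identity(ac_blood_model):
    stable = ad.Radionuclide("stable", math.inf, 0.0, 0.0)
    r = ad.substitute_radionuclide(ac_blood_model, stable)
    assert r.tia == pytest.approx(ad.auc(ac_blood_model), rel=1e-14)


def test_substitution_on_constant_biology_is_pure_physical_decay(at211):
    c0 = 7.5
    model = ad.MultiExponentialModel(terms=((c0, 0.0),), organ_label="x")
    r = ad.substitute_radionuclide(model, at211)
    assert r.tia == pytest.approx(c0 * 7.2 / LN2, rel=1e-12)


def test_substitution_matches_quadrature_and_orders_by_half_life(
    ac_blood_model, ac225, pb212, at211
):
    tias = {}
    for nuc in (ac225, pb212, at211):
        r = ad.substitute_radionuclide(ac_blood_model, nuc)
        numeric, _ = integrate.quad(
            lambda t: float(ac_blood_model.predict(t))
            * math.exp(-nuc.decay_constant_per_h * t),
            0.0,
            1e5,
            limit=500,
        )
        assert r.tia == pytest.approx(numeric, rel=1e-4)
        tias[nuc.label] = r.tia
    assert tias["Ac-225"] > tias["Pb-212"] > tias["At-211"]


@settings(max_examples=40)
@given(
    lam1=st.floats(min_value=0.0, max_value=0.5),
    lam2=st.floats(min_value=0.0, max_value=0.5),
)
def test_substitution_monotone_in_physical_decay(lam1, lam2):
    model = ad.MultiExponentialModel(
        terms=((18.9, LN2 / 6.0), (11.1, LN2 / 19.0)), organ_label="blood"
    )
    lo, hi = sorted((lam1, lam2))
    n_lo = ad.Radionuclide("slow", math.inf, lo, 0.0)
    n_hi = ad.Radionuclide("fast", math.inf, hi, 0.0)
    assert (
        ad.substitute_radionuclide(model, n_lo).tia
        >= ad.substitute_radionuclide(model, n_hi).tia
    )


def test_tail_fraction_vanishes_as_window_extends(ac_blood_model):
    fracs = []
    for t_end in (50.0, 200.0, 800.0):
        t = np.arange(1.0, t_end, 1.0)
        curve = ad.TimeActivityCurve("blood", t, ac_blood_model.predict(t))
        fracs.append(ad.tia_hybrid(curve).tail_fraction)
    assert fracs[0] > fracs[1] > fracs[2]
    assert fracs[2] < 1e-6


def test_ratio_table_trivial_and_ordering(ac225, pb212, at211):
    results = [
        ad.TIAResult("tumor", 200.0, "fit", radionuclide_label="X"),
        ad.TIAResult("blood", 100.0, "fit", radionuclide_label="X"),
    ]
    table = ad.tia_ratio_table(results, "tumor", ["blood", "tumor"])
    assert table.loc["X", "tumor/blood"] == pytest.approx(2.0)
    assert table.loc["X", "tumor/tumor"] == pytest.approx(1.0)

    # slowly accumulating tumor vs clearing blood: the longest-lived nuclide
    # gives the highest tumor-to-blood TIA ratio
    tumor = ad.MultiExponentialModel(
        terms=((-8.0, LN2 / 20.0), (12.0, LN2 / 180.0)), organ_label="tumor"
    )
    blood = ad.MultiExponentialModel(
        terms=((18.9, LN2 / 6.0), (11.1, LN2 / 19.0)), organ_label="blood"
    )
    results = [
        ad.substitute_radionuclide(m, nuc)
        for m in (tumor, blood)
        for nuc in (ac225, pb212, at211)
    ]
    table = ad.tia_ratio_table(results, "tumor", ["blood"])
    ratios = table["tumor/blood"]
    assert ratios["Ac-225"] > ratios["Pb-212"] > ratios["At-211"]


def test_ratio_table_zero_denominator_names_organ(ac225):
    results = [
        ad.TIAResult("tumor", 200.0, "fit"),
        ad.TIAResult("blood", 0.0, "fit"),
    ]
    with pytest.raises(ZeroDivisionError, match="blood"):
        ad.tia_ratio_table(results, "tumor", ["blood"])


def test_two_routes_agree_on_dense_noise_free_biexponential(ac_blood_model):
    t = np.arange(0.25, 400.0, 0.25)
    curve = ad.TimeActivityCurve("blood", t, ac_blood_model.predict(t))
    assert ad.tia_hybrid(curve).tia == pytest.approx(
        ad.tia_from_fit(ac_blood_model).tia, rel=0.02
    )
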