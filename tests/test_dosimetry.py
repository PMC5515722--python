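"""Dose coefficients, kidney curve stripping, marrow rule, prescription."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import alphadose as ad

LN2 = math.log(2.0)


class TestAbsorbedDoseCoefficient:
    def test_dimensional_anchor(self, ac225):
        """4660 %IA*h/g under the full-chain Delta converts to ~738 mGy/kBq."""
        tia = ad.TIAResult("liver", 4660.0, "fit")
        coeff = ad.absorbed_dose_coefficient(tia, ac225)
        assert ad.round_sig(coeff.mgy_per_kbq, 3) == pytest.approx(738.0, rel=0.005)

    def test_linearity_in_tia_and_delta(self, ac225):
        zero = ad.absorbed_dose_coefficient(ad.TIAResult("x", 0.0, "fit"), ac225)
        assert zero.mgy_per_kbq == 0.0
        one = ad.absorbed_dose_coefficient(ad.TIAResult("x", 100.0, "fit"), ac225)
        two = ad.absorbed_dose_coefficient(ad.TIAResult("x", 200.0, "fit"), ac225)
        assert two.mgy_per_kbq == pytest.approx(2 * one.mgy_per_kbq, rel=1e-12)
        doubled = ad.Radionuclide(
            "2x", ac225.physical_half_life_h, ac225.decay_constant_per_h,
            2 * ac225.delta_alpha_j_per_bq_s,
        )
        assert ad.absorbed_dose_coefficient(
            ad.TIAResult("x", 100.0, "fit"), doubled
        ).mgy_per_kbq == pytest.approx(2 * one.mgy_per_kbq, rel=1e-12)

    def test_phi_scales_and_validates(self, ac225):
        tia = ad.TIAResult("x", 100.0, "fit")
        full = ad.absorbed_dose_coefficient(tia, ac225, phi=1.0)
        half = ad.absorbed_dose_coefficient(tia, ac225, phi=0.5)
        assert half.mgy_per_kbq == pytest.approx(full.mgy_per_kbq / 2)
        with pytest.raises(ValueError):
            ad.absorbed_dose_coefficient(tia, ac225, phi=0.0)


class TestKidneyDecomposition:
    def test_zero_free_component_recovered_as_zero(self):
        series = ad.generate_well_counter_series(0.0, 120.0, 0.3, 0.26, seed=4)
        d = ad.decompose_kidney_counts(series)
        total = d.free_bi_conc_bq_g + d.supported_conc_bq_g
        assert d.free_bi_conc_bq_g / total < 0.05

    def test_supported_amplitude_matches_late_interval_rate(self):
        """The slow component barely decays over 4.5 h, so its amplitude
        approximates the mean late-interval count rate / (eff*mass*60)."""
        series = ad.generate_well_counter_series(60.0, 40.0, 0.3, 0.26, seed=8)
        d = ad.decompose_kidney_counts(series)
        late = series.counts[-30:].astype(float).mean()  # >5 fast half-lives in
        implied = late / (series.efficiency * series.mass_g * 60.0)
        assert d.supported_conc_bq_g == pytest.approx(implied, rel=0.15)

    def test_all_zero_counts_flagged(self):
        series = ad.WellCounterSeries(
            interval_start_min=np.arange(270.0),
            interval_min=1.0,
            counts=np.zeros(270, dtype=np.int64),
            efficiency=0.3,
            mass_g=0.3,
        )
        d = ad.decompose_kidney_counts(series)
        assert d.free_bi_conc_bq_g == 0.0 and d.supported_conc_bq_g == 0.0
        assert "no-counts" in d.flags

    def test_short_series_not_identifiable(self):
        series = ad.generate_well_counter_series(
            70.0, 30.0, 0.3, 0.26, duration_h=0.5, seed=2
        )
        with pytest.raises(ValueError):
            ad.decompose_kidney_counts(series)


class TestKidneyDoseWithFreeBi:
    def _free_curve(self, scale):
        t = np.array([1.0, 6.0, 24.0, 72.0, 144.0])
        return ad.TimeActivityCurve("kidneys", t, scale * np.exp(-LN2 / 60.0 * t))

    def test_zero_free_curve_reduces_to_parent(self, ac225):
        kidney_tia = ad.TIAResult("kidneys", 300.0, "fit")
        t = np.array([1.0, 144.0])
        zero = ad.TimeActivityCurve("kidneys", t, np.zeros(2))
        total = ad.kidney_dose_with_free_bi(kidney_tia, zero)
        parent_only = ad.absorbed_dose_coefficient(kidney_tia, ac225)
        assert total.mgy_per_kbq == pytest.approx(parent_only.mgy_per_kbq, rel=1e-12)

    def test_components_sum_exactly_to_total(self):
        kidney_tia = ad.TIAResult("kidneys", 300.0, "fit")
        total = ad.kidney_dose_with_free_bi(kidney_tia, self._free_curve(40.0))
        assert total.components is not None
        assert sum(total.components.values()) == pytest.approx(
            total.mgy_per_kbq, rel=1e-12
        )
        assert total.components["free_bi213"] > 0

    def test_free_share_recovered_from_synthetic_truth(self, ac225, bi213):
        """Free-daughter share of the kidney dose reproduces the analytic share
        computed from the same inputs."""
        kidney_tia = ad.TIAResult("kidneys", 300.0, "fit")
        curve = self._free_curve(40.0)
        total = ad.kidney_dose_with_free_bi(kidney_tia, curve)
        free_tia = ad.tia_hybrid(curve, physical_decay=bi213).tia
        expected_free = free_tia * 3600.0 * bi213.delta_alpha_j_per_bq_s * 1e6
        share = total.components["free_bi213"] / total.mgy_per_kbq
        expected_share = expected_free / (
            expected_free
            + ad.absorbed_dose_coefficient(kidney_tia, ac225).mgy_per_kbq
        )
        assert share == pytest.approx(expected_share, rel=1e-9)


class TestMarrowFromBlood:
    @pytest.mark.parametrize(
        "blood, expected", [(80.4, 28.944), (0.0, 0.0), (100.0, 36.0)]
    )
    def test_fixed_fraction_of_blood(self, blood, expected):
        coeff = ad.marrow_from_blood(ad.DoseCoefficient("blood", blood))
        assert coeff.mgy_per_kbq == pytest.approx(expected, abs=1e-9)
        assert coeff.organ_label == "red marrow"

    def test_report_rounding_convention(self):
        raw = ad.marrow_from_blood(ad.DoseCoefficient("blood", 80.4)).mgy_per_kbq
        assert ad.round_sig(raw, 2) == pytest.approx(29.0)

    def test_factor_validated(self):
        with pytest.raises(ValueError):
            ad.marrow_from_blood(ad.DoseCoefficient("blood", 80.4), factor=0.0)


class TestPrescription:
    COEFFS = [
        ad.DoseCoefficient("liver", 738.0),
        ad.DoseCoefficient("kidneys", 138.0),
        ad.DoseCoefficient("blood", 80.4),
        ad.DoseCoefficient("tumor", 141.0),
    ]

    def test_liver_limited_prescription(self):
        rx = ad.prescribe_activity(self.COEFFS, {"liver": 28.0})
        assert rx.limiting_organ == "liver"
        assert round(rx.administered_kbq) == 38
        assert ad.round_sig(rx.organ_doses_gy["tumor"], 2) == pytest.approx(5.3)

    def test_kidney_limited_prescription(self):
        rx = ad.prescribe_activity(self.COEFFS, {"kidneys": 18.0})
        assert ad.round_sig(rx.administered_kbq, 2) == pytest.approx(130.0)

    def test_most_restrictive_limit_wins(self):
        rx = ad.prescribe_activity(self.COEFFS, {"liver": 28.0, "kidneys": 18.0})
        assert rx.limiting_organ == "liver"  # 38 kBq < 130 kBq
        assert rx.organ_doses_gy["kidneys"] < 18.0

    def test_empty_limits_rejected(self):
        with pytest.raises(ValueError):
            ad.prescribe_activity(self.COEFFS, {})

    def test_missing_coefficient_rejected(self):
        with pytest.raises(KeyError):
            ad.prescribe_activity(self.COEFFS, {"spleen": 10.0})

    @settings(max_examples=60)
    @given(
        coeffs=st.lists(
            st.floats(min_value=1.0, max_value=2000.0), min_size=2, max_size=6
        ),
        limits=st.lists(
            st.floats(min_value=0.5, max_value=60.0), min_size=2, max_size=6
        ),
    )
    def test_no_limited_organ_exceeds_its_limit(self, coeffs, limits):
        k = min(len(coeffs), len(limits))
        cs = [ad.DoseCoefficient(f"o{i}", c) for i, c in enumerate(coeffs[:k])]
        lims = {f"o{i}": l for i, l in enumerate(limits[:k])}
        rx = ad.prescribe_activity(cs, lims)
        for organ, limit in lims.items():
            assert rx.organ_doses_gy[organ] <= limit * (1 + 1e-9)
        assert rx.organ_doses_gy[rx.limiting_organ] == pytest.approx(
            lims[rx.limiting_organ], rel=1e-9
        )

    def test_doses_linear_in_activity(self):
        rx = ad.prescribe_activity(self.COEFFS, {"liver": 28.0})
        for c in self.COEFFS:
            assert rx.organ_doses_gy[c.organ_label] == pytest.approx(
                rx.administered_kbq * c.mgy_per_kbq / 1000.0, rel=1e-12
            )
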