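"""Exact test, tumor volume, wound closure, dose arithmetic, vessel area."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import fisher_exact as scipy_fisher

from chemoconsensus import (
    ContingencyTable2x2,
    DoseSpec,
    ParameterError,
    THIABENDAZOLE_MOLAR_MASS,
    TumorMeasurement,
    dose_convert,
    fisher_exact_2x2,
    tumor_volume,
    vessel_area_fraction,
    wound_closure_ratio,
)


def brute_fisher(a, b, c, d):
    """Exact-integer enumeration oracle for the two-sided conditional test.

    Probabilities share the denominator C(n, c1), so "as-or-less-probable"
    reduces to an exact integer comparison of numerators — no floats.
    """
    n = a + b + c + d
    r1, c1 = a + b, a + c
    obs = math.comb(r1, a) * math.comb(n - r1, c1 - a)
    num = 0
    for k in range(max(0, r1 + c1 - n), min(r1, c1) + 1):
        term = math.comb(r1, k) * math.comb(n - r1, c1 - k)
        if term <= obs:
            num += term
    return num / math.comb(n, c1)


class TestFisherExact:
    def test_ectopic_vessel_counts(self):
        """6/8 affected controls vs 0/9 treated: p = 0.0023 to 2 sig figs."""
        p = fisher_exact_2x2(ContingencyTable2x2(6, 2, 0, 9))
        assert p == pytest.approx(0.0023, abs=5e-5)
        assert float(f"{p:.2g}") == 0.0023

    def test_single_possible_table(self):
        assert fisher_exact_2x2(ContingencyTable2x2(0, 5, 0, 7)) == 1.0

    def test_two_by_two_enumeration(self):
        """(2,0,0,2): C(4,2)=6 arrangements, two extreme tables of prob 1/6."""
        p = fisher_exact_2x2(ContingencyTable2x2(2, 0, 0, 2))
        assert p == pytest.approx(1 / 3)

    def test_agrees_with_integer_oracle_small_tables(self):
        """Every table with total <= 14, against the exact-integer oracle."""
        total_checked = 0
        for a in range(8):
            for b in range(8):
                for c in range(8):
                    for d in range(8):
                        if not 0 < a + b + c + d <= 14:
                            continue
                        p = fisher_exact_2x2(ContingencyTable2x2(a, b, c, d))
                        assert p == pytest.approx(
                            brute_fisher(a, b, c, d), rel=1e-9
                        ), (a, b, c, d)
                        total_checked += 1
        assert total_checked > 1000

    @given(st.integers(0, 12), st.integers(0, 12), st.integers(0, 12),
           st.integers(0, 12))
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_agrees_with_scipy_cross_check(self, a, b, c, d):
        if a + b + c + d == 0:
            return
        ours = fisher_exact_2x2(ContingencyTable2x2(a, b, c, d))
        ref = scipy_fisher([[a, b], [c, d]]).pvalue
        assert ours == pytest.approx(ref, rel=1e-9)

    @given(st.integers(0, 10), st.integers(0, 10), st.integers(0, 10),
           st.integers(0, 10))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_transpose_and_double_swap_invariance(self, a, b, c, d):
        if a + b + c + d == 0:
            return
        p = fisher_exact_2x2(ContingencyTable2x2(a, b, c, d))
        assert fisher_exact_2x2(ContingencyTable2x2(a, c, b, d)) == pytest.approx(p)
        assert fisher_exact_2x2(ContingencyTable2x2(d, c, b, a)) == pytest.approx(p)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ParameterError):
            ContingencyTable2x2(-1, 2, 3, 4)
        with pytest.raises(ParameterError):
            ContingencyTable2x2(0, 0, 0, 0)


class TestTumorVolume:
    def test_worked_examples(self):
        assert tumor_volume(TumorMeasurement(10, 12)) == 600.0
        assert tumor_volume(TumorMeasurement(2, 2)) == 4.0

    @given(st.floats(0.1, 50), st.floats(0.1, 50), st.floats(1.1, 3))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_cubic_scaling(self, w, l, s):
        v1 = tumor_volume(TumorMeasurement(w, l))
        v2 = tumor_volume(TumorMeasurement(s * w, s * l))
        assert v2 == pytest.approx(s**3 * v1, rel=1e-9)

    def test_reversed_axes_swapped_not_rejected(self):
        tm = TumorMeasurement(12, 10)  # caliper axes given backwards
        assert (tm.width, tm.length) == (10, 12)
        assert tumor_volume(tm) == 600.0

    def test_nonpositive_rejected(self):
        with pytest.raises(ParameterError):
            TumorMeasurement(0, 5)


class TestWoundClosure:
    @pytest.mark.parametrize(
        "a0, at, expected", [(100, 40, 0.6), (7, 7, 0.0), (55, 0, 1.0)]
    )
    def test_worked_examples(self, a0, at, expected):
        assert wound_closure_ratio(a0, at) == pytest.approx(expected)

    def test_negative_closure_reported_not_clamped(self):
        assert wound_closure_ratio(100, 120) == pytest.approx(-0.2)

    def test_zero_initial_area_rejected(self):
        with pytest.raises(ParameterError):
            wound_closure_ratio(0, 10)


class TestDoseConvert:
    def test_mouse_dose_is_250_uM_equivalent(self):
        """1 mg into a 20 g mouse: 50 mg/kg, ~250 uM-equivalent."""
        mg_kg, umol_kg = dose_convert(DoseSpec(mass=1.0, body_mass=20.0))
        assert mg_kg == pytest.approx(50.0)
        assert umol_kg == pytest.approx(1.0 / 0.020 / 201.25 * 1000)
        assert float(f"{umol_kg:.2g}") == 250.0

    def test_human_max_daily_dose(self):
        """3 g for a 60 kg patient is exactly 50 mg/kg."""
        mg_kg, _ = dose_convert(DoseSpec(mass=3000.0, body_mass=60000.0))
        assert mg_kg == 50.0

    def test_unit_identity(self):
        mg_kg, umol_kg = dose_convert(
            DoseSpec(mass=0.001, body_mass=1.0, molar_mass=1000.0)
        )
        assert mg_kg == pytest.approx(1.0)
        assert umol_kg == pytest.approx(1.0)

    def test_density_scales_molarity_only(self):
        mg1, um1 = dose_convert(DoseSpec(1.0, 20.0))
        mg2, um2 = dose_convert(DoseSpec(1.0, 20.0, density_assumption=2.0))
        assert mg1 == mg2
        assert um2 == pytest.approx(um1 / 2.0)

    def test_molar_mass_constant(self):
        # C10 H7 N3 S
        mw = 10 * 12.011 + 7 * 1.008 + 3 * 14.007 + 32.06
        assert THIABENDAZOLE_MOLAR_MASS == pytest.approx(mw, abs=0.01)

    def test_nonpositive_rejected(self):
        with pytest.raises(ParameterError):
            DoseSpec(mass=0.0, body_mass=20.0)


class TestVesselArea:
    def test_worked_examples(self):
        frac, count = vessel_area_fraction(np.array([[0, 0], [5, 5]]), 1.0)
        assert (frac, count) == (0.5, 2)
        frac, _ = vessel_area_fraction(np.array([[0, 0], [5, 5]]), 99.0)
        assert frac == 0.0

    def test_constructed_quarter_fixture(self):
        img = np.zeros((20, 20))
        img[:10, :10] = 7.0  # exactly 100 of 400 pixels above threshold
        frac, count = vessel_area_fraction(img, 1.0)
        assert frac == 0.25 and count == 100

    def test_threshold_strictness(self):
        img = np.full((4, 4), 3.0)
        assert vessel_area_fraction(img, 3.0)[0] == 0.0  # strict ">"

    def test_monotone_non_increasing_in_threshold(self):
        rng = np.random.default_rng(8)
        img = rng.uniform(0, 10, size=(30, 30))
        fracs = [vessel_area_fraction(img, t)[0] for t in np.linspace(-1, 11, 25)]
        assert all(a >= b for a, b in zip(fracs, fracs[1:]))

    def test_empty_image_rejected(self):
        with pytest.raises(ParameterError):
            vessel_area_fraction(np.empty((0, 3)), 1.0)
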