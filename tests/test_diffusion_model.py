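"""Unit and property tests for the steady-state concentration fields."""

import math
from dataclasses import replace

import numpy as np
import pytest
from scipy import integrate

from quorumsim import (
    ColonyParameters,
    ConcentrationValue,
    colony_concentration_closed_form,
    colony_concentration_quadrature,
    erf_profile,
    single_cell_concentration,
    to_nanomolar,
)
from quorumsim.diffusion_model import (
    ORIGIN_PREFACTOR_SERIES,
    ORIGIN_PREFACTOR_TAYLOR,
    from_nanomolar,
    single_cell_origin_limit,
)


def quad_erf(x: float) -> float:
    """Independent oracle: direct quadrature of (2/sqrt(pi)) exp(-h^2)."""
    val, _ = integrate.quad(lambda h: 2.0 / math.sqrt(math.pi) * math.exp(-h * h), 0, x)
    return val


class TestErfProfile:
    @pytest.mark.parametrize(
        "x,expected,tol",
        [
            (0.0, 0.0, 0.0),                  # empty integration interval
            (1.0, 0.8427007929497149, 1e-12),  # frozen from quad_erf(1.0)
            (10.0, 1.0, 1e-12),               # asymptotic limit
        ],
    )
    def test_reference_values(self, x, expected, tol):
        assert erf_profile(x) == pytest.approx(expected, abs=tol)

    def test_matches_quadrature_oracle(self):
        for x in [0.1, 0.5, 1.3, 2.7]:
            assert erf_profile(x) == pytest.approx(quad_erf(x), rel=1e-10)

    def test_monotonically_increasing(self):
        xs = np.linspace(0, 4, 100)
        assert np.all(np.diff(erf_profile(xs)) > 0)

    @pytest.mark.parametrize("bad", [-0.5, np.nan, np.inf])
    def test_rejects_invalid_input(self, bad):
        with pytest.raises(ValueError):
            erf_profile(bad)


class TestSingleCell:
    P, D, WS = 5000.0, 1e-6, 1e-4  # molecules/cell-s, cm^2/s, cm (1 um)

    def test_far_from_cell_matches_point_source(self):
        # at r = 100 Ws the error-function factor is already 1
        r = 1e-2
        c = single_cell_concentration(r, self.P, self.D, self.WS)
        assert c.unit == ConcentrationValue.MOLECULES
        assert c.value == pytest.approx(self.P / (2 * math.pi * self.D * r), rel=1e-12)
        assert c.value == pytest.approx(7.9577e10, rel=1e-4)

    def test_far_field_limit_property(self):
        for r_over_ws in [50, 500, 5000]:
            r = r_over_ws * self.WS
            c = single_cell_concentration(r, self.P, self.D, self.WS)
            assert c.value * 2 * math.pi * self.D * r / self.P == pytest.approx(
                1.0, abs=1e-12
            )

    def test_origin_limit_value(self):
        c = single_cell_concentration(0.0, self.P, self.D, self.WS)
        expected = self.P / (math.sqrt(2) * math.pi**1.5 * self.D * self.WS)
        assert c.value == pytest.approx(expected, rel=1e-12)
        assert single_cell_origin_limit(self.P, self.D, self.WS) == pytest.approx(
            expected
        )

    def test_printed_taylor_prefactor_is_half_the_series_limit(self):
        # the two published origin prefactors differ by exactly 2; the field
        # uses the series-consistent one so the profile stays continuous
        assert ORIGIN_PREFACTOR_SERIES == pytest.approx(
            2.0 * ORIGIN_PREFACTOR_TAYLOR, rel=1e-14
        )

    def test_continuity_across_small_radius_switch(self):
        switch = 1e-6 * self.WS
        below = single_cell_concentration(switch * 0.999, self.P, self.D, self.WS)
        above = single_cell_concentration(switch * 1.001, self.P, self.D, self.WS)
        assert below.value == pytest.approx(above.value, rel=1e-9)

    def test_monotonically_non_increasing_in_r(self):
        rs = np.concatenate([[0.0], np.logspace(-8, -1, 80)])
        vals = [
            single_cell_concentration(r, self.P, self.D, self.WS).value for r in rs
        ]
        assert np.all(np.diff(vals) <= 0)

    def test_rejects_negative_radius_and_bad_params(self):
        with pytest.raises(ValueError):
            single_cell_concentration(-1e-3, self.P, self.D, self.WS)
        with pytest.raises(ValueError):
            single_cell_concentration(1e-3, -self.P, self.D, self.WS)


class TestColonyConcentration:
    def test_reference_scenario_value(self, reference_colony):
        # leading term P n R^2 / (2 D) = 5.0625e12; bracket corrections are
        # O(Ws^2/R^2) ~ 5e-6 here
        c = colony_concentration_closed_form(reference_colony)
        assert c.value == pytest.approx(5.0625e12, rel=1e-4)
        assert to_nanomolar(c).value == pytest.approx(8.4064, rel=1e-4)

    def test_bracket_tends_to_one_for_thin_cells(self, reference_colony):
        leading = (
            reference_colony.production_rate
            * reference_colony.cell_density
            * reference_colony.colony_radius**2
            / (2 * reference_colony.diffusion_coefficient)
        )
        slim = replace(reference_colony, cell_width=1e-7)  # Ws/R = 2.2e-6
        c = colony_concentration_closed_form(slim)
        assert c.value == pytest.approx(leading, rel=1e-10)

    def test_linearity_in_p_and_inverse_d(self, reference_colony):
        base = colony_concentration_closed_form(reference_colony).value
        double_p = replace(reference_colony, production_rate=10000.0)
        half_d = replace(reference_colony, diffusion_coefficient=2e-6)
        assert colony_concentration_closed_form(double_p).value == pytest.approx(
            2 * base, rel=1e-14
        )
        assert colony_concentration_closed_form(half_d).value == pytest.approx(
            base / 2, rel=1e-14
        )

    def test_monotone_in_every_parameter(self, reference_colony):
        base = colony_concentration_closed_form(reference_colony).value
        up = {
            "production_rate": 6000.0,
            "cell_density": 2e6,
            "colony_radius": 0.06,
        }
        for field, value in up.items():
            c = colony_concentration_closed_form(
                replace(reference_colony, **{field: value})
            ).value
            assert c > base, field
        c = colony_concentration_closed_form(
            replace(reference_colony, diffusion_coefficient=2e-6)
        ).value
        assert c < base

    def test_warns_for_colony_under_ten_cell_widths(self, reference_colony):
        small = replace(reference_colony, colony_radius=5e-4)  # 5 cell widths
        with pytest.warns(UserWarning, match="10 cell widths"):
            colony_concentration_closed_form(small)

    def test_quadrature_r_squared_scaling(self, reference_colony):
        # for R >> Ws the integral is R^2/2, so doubling R quadruples N
        doubled = replace(
            reference_colony, colony_radius=2 * reference_colony.colony_radius
        )
        ratio = (
            colony_concentration_quadrature(doubled).value
            / colony_concentration_quadrature(reference_colony).value
        )
        assert ratio == pytest.approx(4.0, rel=1e-3)

    def test_oracle_equivalence_randomized(self):
        """Closed form vs independent quadrature over the physical range."""
        rng = np.random.default_rng(20260920)
        worst_all, worst_large = 0.0, 0.0
        for _ in range(100):
            ws = 10 ** rng.uniform(-4.5, -3.5)
            ratio = 10 ** rng.uniform(np.log10(50), np.log10(5000))
            params = ColonyParameters(
                production_rate=10 ** rng.uniform(2.5, 4.7),
                cell_density=10 ** rng.uniform(4, 7),
                colony_radius=ratio * ws,
                diffusion_coefficient=10 ** rng.uniform(-6, -5),
                cell_width=ws,
            )
            cf = colony_concentration_closed_form(params).value
            qd = colony_concentration_quadrature(params).value
            rel = abs(cf - qd) / qd
            worst_all = max(worst_all, rel)
            if ratio > 300:
                worst_large = max(worst_large, rel)
        assert worst_all < 1e-2
        assert worst_large < 1e-3

    def test_parameter_validation(self):
        with pytest.raises(ValueError, match="cell_width"):
            ColonyParameters(5000, 1e6, 0.05, 1e-6, -1e-4)
        with pytest.raises(ValueError, match="colony_radius"):
            ColonyParameters(5000, 1e6, 5e-5, 1e-6, 1e-4)  # R < Ws


class TestUnitConversions:
    def test_one_nanomolar_definition(self):
        c = ConcentrationValue(6.02214076e11, ConcentrationValue.MOLECULES)
        assert to_nanomolar(c).value == pytest.approx(1.0, rel=1e-12)

    def test_zero_maps_to_zero(self):
        c = ConcentrationValue(0.0, ConcentrationValue.MOLECULES)
        assert to_nanomolar(c).value == 0.0

    def test_round_trip(self):
        c = ConcentrationValue(5.06e12, ConcentrationValue.MOLECULES)
        nm = to_nanomolar(c)
        assert nm.value == pytest.approx(8.4, rel=2e-3)
        back = from_nanomolar(nm)
        assert back.value == pytest.approx(c.value, rel=1e-12)

    def test_wrong_unit_tag_rejected(self):
        nm = ConcentrationValue(1.0, ConcentrationValue.NANOMOLAR)
        with pytest.raises(ValueError, match="unit"):
            to_nanomolar(nm)
        with pytest.raises(ValueError, match="unit"):
            from_nanomolar(ConcentrationValue(1.0, ConcentrationValue.MOLECULES))
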