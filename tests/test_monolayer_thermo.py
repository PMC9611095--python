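import numpy as np
import pytest

from monofilm.errors import DomainError, InsufficientDataError, ValidationError
from monofilm.isotherm_io import Isotherm, extract_compression_branch
from monofilm.monolayer_thermo import (
    area_at_pressure,
    classify_phase_state,
    compressibility_curve,
    detect_transition_pressure,
    excess_area,
    excess_gibbs_energy,
    ideal_mixing_area,
)
from monofilm.synthetic_data import (
    ExcessParams,
    Plateau,
    PressureGrid,
    PureEOSParams,
    excess_gibbs_truth,
    generate_mixture_isotherm,
    generate_pure_isotherm,
)

KT = 428.2


def ideal_gas_isotherm(pi_min=2.0, pi_max=30.0, n=600):
    """pi * A = kT exactly, sampled uniformly in pressure."""
    pi = np.linspace(pi_min, pi_max, n)
    return Isotherm(KT / pi, pi, {"compound_id": "ideal-gas"})


class TestAreaAtPressure:
    def test_volmer_closed_form(self, lipid):
        iso = generate_pure_isotherm(lipid, PressureGrid(0, 35, 0.05))
        r = area_at_pressure(iso, 10.0)
        assert r.attained
        # closed form: 40 + 428.2/15.7 = 67.27 A^2
        assert r.area == pytest.approx(40.0 + KT / 15.7, abs=0.01)

    def test_exact_grid_hit(self):
        iso = Isotherm(
            np.array([120.0, 110.0, 100.0, 90.0]),
            np.array([1.0, 5.0, 10.0, 20.0]),
            {"noise_sigma": 0.0},
        )
        r = area_at_pressure(iso, 10.0)
        assert r.area == 100.0  # tabulated point, no interpolation

    def test_non_spreading_unattained(self, non_spreading, grid):
        iso = generate_pure_isotherm(non_spreading, grid, noise_sigma=0.1, seed=0)
        r = area_at_pressure(iso, 10.0)
        assert not r.attained
        assert r.area == 0.0

    def test_above_max_pressure_unattained(self, lipid):
        iso = generate_pure_isotherm(lipid, PressureGrid(0, 20, 0.25))
        r = area_at_pressure(iso, 25.0)
        assert not r.attained and r.area == 0.0

    def test_unsorted_branch_rejected(self):
        iso = Isotherm(
            np.array([120.0, 100.0, 110.0, 90.0]),
            np.array([1.0, 5.0, 3.0, 20.0]),
            {"noise_sigma": 0.1},
        )
        with pytest.raises(ValidationError):
            area_at_pressure(iso, 10.0)

    def test_first_upward_crossing_on_wiggly_pressure(self):
        # pressure dips back below 10 then re-crosses: largest-area crossing wins
        iso = Isotherm(
            np.array([120.0, 110.0, 100.0, 95.0, 90.0, 85.0]),
            np.array([5.0, 9.0, 11.0, 9.5, 10.5, 15.0]),
            {"noise_sigma": 0.5},
        )
        r = area_at_pressure(iso, 10.0)
        assert r.area == pytest.approx(105.0)  # between 110 (9) and 100 (11)


class TestIdealAndExcessArea:
    def test_midpoint(self):
        assert ideal_mixing_area(80.0, 40.0, 0.5) == 60.0

    def test_endpoint(self):
        assert ideal_mixing_area(80.0, 40.0, 0.0) == 80.0

    def test_unattained_component_convention(self):
        # component 2 never spreads: recorded area 0, line collapses to x1*a1
        assert ideal_mixing_area(80.0, 0.0, 0.25) == 0.75 * 80.0

    def test_excess_area_sign(self):
        assert excess_area(70.0, 80.0, 40.0, 0.5) == pytest.approx(10.0)
        assert excess_area(50.0, 80.0, 40.0, 0.5) == pytest.approx(-10.0)

    def test_excess_area_endpoint_zero(self):
        assert excess_area(80.0, 80.0, 40.0, 0.0) == 0.0

    def test_generator_ground_truth_at_liftoff(self, lipid, compound, grid):
        mix = generate_mixture_isotherm(
            lipid, compound, 0.25, ExcessParams(a_ex=5.0, pi_s=20.0), grid
        )
        iso1 = generate_pure_isotherm(lipid, grid)
        iso2 = generate_pure_isotherm(compound, grid)
        pi = 1.0
        a12 = area_at_pressure(mix, pi).area
        a1 = area_at_pressure(iso1, pi).area
        a2 = area_at_pressure(iso2, pi).area
        expected = 4 * 0.25 * 0.75 * 5.0 * np.exp(-pi / 20.0)
        assert excess_area(a12, a1, a2, 0.25) == pytest.approx(expected, abs=0.02)


class TestExcessGibbs:
    def test_ideal_mixture_zero(self, study_builder):
        branches = study_builder(ExcessParams(a_ex=0.0))
        iso1, iso2 = branches[0], branches[1]
        for mix in branches[2:]:
            dg = excess_gibbs_energy(mix, iso1, iso2, mix.x2, 30.0)
            assert abs(dg) < 1.0

    def test_closed_form_recovery(self, lipid, compound, grid):
        ex = ExcessParams(a_ex=5.0, pi_s=20.0)
        iso1 = generate_pure_isotherm(lipid, grid)
        iso2 = generate_pure_isotherm(compound, grid)
        mix = generate_mixture_isotherm(lipid, compound, 0.25, ex, grid)
        dg = excess_gibbs_energy(mix, iso1, iso2, 0.25, 30.0)
        # 6.02214 * 3.75 * 20 * (1 - e^-1.5) = 350.9 J/mol
        assert dg == pytest.approx(excess_gibbs_truth(ex, 0.25, 30.0), rel=0.01)

    def test_constant_excess_unit_conversion(self, lipid, compound, grid):
        ex = ExcessParams(a_ex=5.0)  # pi_s -> inf
        iso1 = generate_pure_isotherm(lipid, grid)
        iso2 = generate_pure_isotherm(compound, grid)
        mix = generate_mixture_isotherm(lipid, compound, 0.5, ex, grid)
        dg = excess_gibbs_energy(mix, iso1, iso2, 0.5, 20.0)
        assert dg == pytest.approx(6.02214 * 5.0 * 20.0, rel=0.01)

    def test_endpoint_exactness(self, lipid, compound, grid):
        iso1 = generate_pure_isotherm(lipid, grid)
        iso2 = generate_pure_isotherm(compound, grid)
        assert excess_gibbs_energy(iso1, iso1, iso2, 0.0, 30.0) == 0.0
        assert excess_gibbs_energy(iso2, iso1, iso2, 1.0, 30.0) == 0.0

    def test_unattained_pi_star_rejected(self, lipid, compound):
        grid = PressureGrid(0, 20, 0.25)
        iso1 = generate_pure_isotherm(lipid, grid)
        iso2 = generate_pure_isotherm(compound, grid)
        mix = generate_mixture_isotherm(lipid, compound, 0.25, ExcessParams(), grid)
        with pytest.raises(DomainError):
            excess_gibbs_energy(mix, iso1, iso2, 0.25, 25.0)

    def test_fundamental_theorem(self, lipid, compound, grid):
        # numerical d(dG)/dpi* equals 6.02214 * A_ex(pi*) within 2%
        ex = ExcessParams(a_ex=5.0, pi_s=20.0)
        iso1 = generate_pure_isotherm(lipid, grid)
        iso2 = generate_pure_isotherm(compound, grid)
        mix = generate_mixture_isotherm(lipid, compound, 0.25, ex, grid)
        h = 1.0
        for pi_star in (10.0, 20.0):
            d = (
                excess_gibbs_energy(mix, iso1, iso2, 0.25, pi_star + h)
                - excess_gibbs_energy(mix, iso1, iso2, 0.25, pi_star - h)
            ) / (2 * h)
            a_ex = 6.02214 * ex.area_excess(np.array([pi_star]), 0.25)[0]
            assert d == pytest.approx(a_ex, rel=0.02)

    def test_monotone_decay_of_excess_area(self, study_builder):
        branches = study_builder(ExcessParams(a_ex=5.0, pi_s=20.0))
        iso1, iso2 = branches[0], branches[1]
        for mix in branches[2:]:
            devs = []
            for pi in (10.0, 20.0, 30.0):
                a12 = area_at_pressure(mix, pi).area
                a1 = area_at_pressure(iso1, pi).area
                a2 = area_at_pressure(iso2, pi).area
                devs.append(abs(excess_area(a12, a1, a2, mix.x2)))
            assert devs[0] > devs[1] > devs[2]


class TestCompressibility:
    def test_ideal_gas_closed_form(self):
        cc = compressibility_curve(ideal_gas_isotherm())
        sel = slice(15, -15)  # away from branch endpoints
        rel = np.abs(cc.cs_inv[sel] - cc.pressures[sel]) / cc.pressures[sel]
        assert np.max(rel) < 0.005

    def test_linear_isotherm_closed_form(self):
        areas = np.linspace(110.0, 40.0, 400)
        iso = Isotherm(areas, 0.5 * (115.0 - areas), {})
        cc = compressibility_curve(iso)
        # Cs^-1 = A * m; at A = 50: 25 mN/m
        a_sorted = (115.0 - 2 * cc.pressures)  # recover area from pressure
        i = np.argmin(np.abs(a_sorted - 50.0))
        assert cc.cs_inv[i] == pytest.approx(25.0, rel=0.005)

    def test_plateau_drives_cs_to_zero(self, grid):
        p = PureEOSParams(
            id="p", A0=40.0, pi_c=5.7,
            plateau=Plateau(pi_t=15.0, delta_A=25.0, width=0.1),
        )
        iso = generate_pure_isotherm(p, PressureGrid(0, 35, 0.1))
        cc = compressibility_curve(iso)
        near = np.abs(cc.pressures - 15.0) < 1.0
        assert np.min(cc.cs_inv[near]) < 1.0

    def test_nonnegative_on_noiseless_branch(self, lipid, plateau_params, grid):
        for p in (lipid, plateau_params):
            cc = compressibility_curve(generate_pure_isotherm(p, grid))
            assert np.all(cc.cs_inv >= 0.0)

    def test_window_validation(self, lipid, grid):
        iso = generate_pure_isotherm(lipid, grid)
        with pytest.raises(ValidationError):
            compressibility_curve(iso, window=10)
        with pytest.raises(ValidationError):
            compressibility_curve(iso, window=5, order=5)

    def test_short_branch_rejected(self, lipid):
        iso = generate_pure_isotherm(lipid, PressureGrid(0, 2, 0.25))
        with pytest.raises(InsufficientDataError):
            compressibility_curve(iso, window=11)

    def test_phase_labels_attached(self, lipid, grid):
        cc = compressibility_curve(generate_pure_isotherm(lipid, grid))
        assert len(cc.phases) == len(cc)
        assert set(cc.phases) <= {"gaseous", "LE", "LE-LC", "LC", "solid"}


class TestPhaseClassification:
    @pytest.mark.parametrize(
        "value,label",
        [
            (5.0, "gaseous"),
            (12.49, "gaseous"),
            (12.5, "LE"),
            (30.0, "LE"),
            (50.0, "LE-LC"),
            (99.9, "LE-LC"),
            (100.0, "LC"),
            (150.0, "LC"),
            (250.0, "solid"),
            (400.0, "solid"),
        ],
    )
    def test_bands(self, value, label):
        assert classify_phase_state(value) == label

    def test_negative_rejected(self):
        with pytest.raises(DomainError):
            classify_phase_state(-1.0)


class TestTransitionDetection:
    def test_noiseless_plateau_detected(self, plateau_params, grid):
        cc = compressibility_curve(generate_pure_isotherm(plateau_params, grid))
        t = detect_transition_pressure(cc)
        assert t is not None
        assert t == pytest.approx(15.0, abs=0.5)

    def test_pure_volmer_none(self, lipid, grid):
        cc = compressibility_curve(generate_pure_isotherm(lipid, grid))
        assert detect_transition_pressure(cc) is None

    def test_shallow_plateau_gated_out(self, grid):
        p = PureEOSParams(
            id="s", A0=40.0, pi_c=5.7,
            plateau=Plateau(pi_t=15.0, delta_A=1.0, width=2.0),
        )
        cc = compressibility_curve(generate_pure_isotherm(p, grid))
        assert detect_transition_pressure(cc, min_prominence=5.0) is None

    def test_noisy_recovery_single_seed(self, plateau_params, grid):
        iso = generate_pure_isotherm(plateau_params, grid, noise_sigma=0.1, seed=3)
        cc = compressibility_curve(extract_compression_branch(iso))
        t = detect_transition_pressure(cc)
        assert t == pytest.approx(15.0, abs=0.5)

    def test_too_short_curve(self, lipid, grid):
        cc = compressibility_curve(generate_pure_isotherm(lipid, grid))
        cc.pressures = cc.pressures[:4]
        cc.cs_inv = cc.cs_inv[:4]
        with pytest.raises(InsufficientDataError):
            detect_transition_pressure(cc)
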