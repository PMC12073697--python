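"""Flory-Huggins solubility fitting and the phase/state diagram."""

import numpy as np
import pytest

from asdkit.calorimetry import GordonTaylorModel
from asdkit.errors import DomainError
from asdkit.solubility import (
    FloryHugginsModel,
    PhaseDiagram,
    SolubilityPoint,
    build_phase_diagram,
    classify_state,
    fh_residual,
    fit_chi,
    latreche_points,
    lambda_ratio,
    solve_solubility_temperature,
    volume_fraction,
)
from asdkit import reference_data as rd


@pytest.fixture
def fh_model():
    """Drug/polymer constants of the terfenadine / PVP K12 system."""
    return FloryHugginsModel(tm_C=150.0, dhm_J_mol=54.2e3, rho_drug=1.05,
                             rho_polymer=1.17, m_drug=471.7, mw_polymer=2500.0)


@pytest.fixture
def gt_model():
    return GordonTaylorModel(tg_drug=60.0, tg_polymer=106.0, k=0.76)


class TestVolumeFractionAndLambda:
    def test_endpoints(self, fh_model):
        assert volume_fraction(0.0, fh_model) == 0.0
        assert volume_fraction(1.0, fh_model) == 1.0

    def test_equal_densities_identity(self):
        m = FloryHugginsModel(tm_C=150.0, dhm_J_mol=5e4, rho_drug=1.1,
                              rho_polymer=1.1, m_drug=400.0, mw_polymer=2500.0)
        x = np.linspace(0, 1, 11)
        np.testing.assert_allclose(volume_fraction(x, m), x, rtol=1e-14)

    def test_hand_arithmetic_value(self, fh_model):
        # x/rho_d / (x/rho_d + (1-x)/rho_p) at x = 0.66
        expected = (0.66 / 1.05) / (0.66 / 1.05 + 0.34 / 1.17)
        assert volume_fraction(0.66, fh_model) == pytest.approx(expected,
                                                                rel=1e-14)
        assert expected == pytest.approx(0.684, abs=5e-4)

    def test_strictly_increasing(self, fh_model):
        x = np.linspace(0, 1, 101)
        assert np.all(np.diff(volume_fraction(x, fh_model)) > 0)

    def test_lambda_value_and_scalings(self, fh_model):
        lam = lambda_ratio(fh_model)
        assert lam == pytest.approx(2500 * 1.05 / (1.17 * 471.7), rel=1e-14)
        assert lam == pytest.approx(4.76, abs=0.01)
        doubled = FloryHugginsModel(tm_C=150.0, dhm_J_mol=54.2e3,
                                    rho_drug=1.05, rho_polymer=1.17,
                                    m_drug=471.7, mw_polymer=5000.0)
        assert lambda_ratio(doubled) == pytest.approx(2 * lam, rel=1e-14)
        sym = FloryHugginsModel(tm_C=150.0, dhm_J_mol=5e4, rho_drug=1.0,
                                rho_polymer=1.0, m_drug=500.0,
                                mw_polymer=500.0)
        assert lambda_ratio(sym) == 1.0


class TestFHResidual:
    def test_melting_point_anchor(self, fh_model):
        assert fh_residual(1.0, 150.0, fh_model, chi=-2.3) == pytest.approx(
            0.0, abs=1e-14)

    def test_small_residual_at_measured_saturation(self, fh_model):
        # independent evaluation of both sides at the 140 degC point
        r = fh_residual(0.66, 140.0, fh_model, chi=-2.3)
        phi = volume_fraction(0.66, fh_model)
        lhs = 54.2e3 / 8.314 * (1 / 423.15 - 1 / 413.15)
        rhs = (np.log(phi) + (1 - 1 / fh_model.lam) * (1 - phi)
               - 2.3 * (1 - phi) ** 2)
        assert r == pytest.approx(lhs - rhs, rel=1e-12)
        assert abs(r) < 0.05

    def test_affine_in_chi_with_slope_one_minus_phi_squared(self, fh_model):
        phi = volume_fraction(0.5, fh_model)
        r1 = fh_residual(0.5, 130.0, fh_model, chi=-1.0)
        r2 = fh_residual(0.5, 130.0, fh_model, chi=-3.0)
        assert (r2 - r1) / 2.0 == pytest.approx((1 - phi) ** 2, rel=1e-12)

    def test_zero_drug_fraction_rejected(self, fh_model):
        with pytest.raises(DomainError):
            fh_residual(0.0, 130.0, fh_model, chi=-2.3)


class TestSolveSolubilityTemperature:
    def test_pure_drug_limit_reaches_melting_point(self, fh_model):
        m = fh_model.with_chi(-2.3)
        assert solve_solubility_temperature(0.9999, m) == pytest.approx(
            150.0, abs=0.05)

    def test_saturation_point_near_its_annealing_temperature(self, fh_model):
        m = fh_model.with_chi(-2.3)
        t = solve_solubility_temperature(0.66, m)
        # grid-scan oracle on the residual
        grid = np.linspace(100.0, 200.0, 4001)
        vals = np.array([fh_residual(0.66, g, m) for g in grid])
        brute = grid[np.argmin(np.abs(vals))]
        assert t == pytest.approx(brute, abs=0.05)
        assert t == pytest.approx(140.0, abs=2.0)

    def test_monotone_in_composition(self, fh_model):
        m = fh_model.with_chi(-2.3)
        ts = [solve_solubility_temperature(x, m)
              for x in (0.4, 0.5, 0.66, 0.8, 0.95)]
        assert all(a < b for a, b in zip(ts, ts[1:]))


class TestFitChi:
    def test_measured_saturation_points_give_reported_chi(self, fh_model):
        pts = [SolubilityPoint(t, None, x) for t, x in
               zip(rd.SOLUBILITY_ANNEALING.t_anneal_C,
                   rd.SOLUBILITY_ANNEALING.x_sat)]
        m = fit_chi(pts, fh_model)
        assert m.chi == pytest.approx(-2.3, abs=0.15)

    def test_exact_recovery_of_synthetic_chi(self, fh_model):
        truth = fh_model.with_chi(-5.0)
        pts = []
        for x in (0.3, 0.5, 0.7, 0.9):
            t = solve_solubility_temperature(x, truth)
            pts.append(SolubilityPoint(t, None, x))
        m = fit_chi(pts, fh_model)
        assert m.chi == pytest.approx(-5.0, abs=1e-8)

    def test_closed_form_matches_iterative_minimiser(self, fh_model):
        from scipy.optimize import minimize_scalar
        pts = [SolubilityPoint(t, None, x) for t, x in
               zip(rd.SOLUBILITY_ANNEALING.t_anneal_C,
                   rd.SOLUBILITY_ANNEALING.x_sat)]
        m = fit_chi(pts, fh_model)

        def sse(chi):
            return sum(fh_residual(p.x_sat, p.t_anneal, fh_model, chi=chi) ** 2
                       for p in pts)
        it = minimize_scalar(sse, bounds=(-10, 5), method="bounded",
                             options={"xatol": 1e-12})
        assert m.chi == pytest.approx(it.x, abs=1e-6)

    def test_pointwise_chis_bracket_the_joint_fit(self, fh_model):
        chis = []
        for _, row in rd.SOLUBILITY_ANNEALING.iterrows():
            phi = volume_fraction(row.x_sat, fh_model)
            lhs = fh_model.dhm_J_mol / 8.314 * (
                1 / fh_model.tm_K - 1 / (row.t_anneal_C + 273.15))
            rest = np.log(phi) + (1 - 1 / fh_model.lam) * (1 - phi)
            chis.append((lhs - rest) / (1 - phi) ** 2)
        joint = fit_chi([SolubilityPoint(t, None, x) for t, x in
                         zip(rd.SOLUBILITY_ANNEALING.t_anneal_C,
                             rd.SOLUBILITY_ANNEALING.x_sat)], fh_model).chi
        assert min(chis) < joint < max(chis)
        assert min(chis) == pytest.approx(-2.6, abs=0.1)
        assert max(chis) == pytest.approx(-2.0, abs=0.1)


class TestLatrechePoints:
    def test_annealing_records_convert_to_saturation(self, gt_model):
        pts, errs = latreche_points([(140.0, 73.0), (130.0, 81.0)], gt_model)
        assert not errs
        assert pts[0].t_anneal == 130.0
        assert pts[1].x_sat == pytest.approx(0.66, abs=0.01)
        assert pts[0].x_sat == pytest.approx(0.48, abs=0.01)

    def test_out_of_range_tg_yields_error_entry(self, gt_model):
        pts, errs = latreche_points([(140.0, 73.0), (145.0, 60.0)], gt_model)
        assert len(pts) == 1 and len(errs) == 1
        assert errs[0]["t_anneal"] == 145.0

    def test_round_trip_through_gt(self, gt_model):
        from asdkit.calorimetry import gt_eval
        for x in (0.2, 0.5, 0.8):
            tg = gt_eval(gt_model, x)
            pts, _ = latreche_points([(120.0, tg)], gt_model)
            assert pts[0].x_sat == pytest.approx(x, abs=1e-12)


class TestPhaseDiagram:
    @pytest.fixture
    def diagram(self, gt_model, fh_model):
        return build_phase_diagram(gt_model, fh_model.with_chi(-2.3))

    def test_grid_monotone_in_x(self, diagram):
        g = diagram.grid
        assert g.x_drug.is_monotonic_increasing
        assert np.all(np.diff(g.tg_C) < 0)

    def test_curves_intersect_exactly_once(self, diagram):
        g = diagram.grid.dropna()
        sign = np.sign(g.tg_C.to_numpy() - g.t_solubility_C.to_numpy())
        crossings = np.sum(np.diff(sign) != 0)
        assert crossings == 1

    def test_json_round_trip(self, diagram):
        back = PhaseDiagram.from_json(diagram.to_json())
        assert back.gt_model.k == diagram.gt_model.k
        assert back.fh_model.chi == diagram.fh_model.chi
        np.testing.assert_allclose(back.grid.tg_C, diagram.grid.tg_C)
        np.testing.assert_allclose(back.grid.t_solubility_C,
                                   diagram.grid.t_solubility_C)

    def test_classification_of_characteristic_points(self, diagram):
        assert classify_state(0.66, 145.0, diagram).primary == \
            "undersaturated-liquid"
        room = classify_state(0.90, 25.0, diagram)
        assert room.primary == "glassy" and room.supersaturated
        assert classify_state(0.0, 25.0, diagram).primary == "pure-polymer"
        assert classify_state(1.0, 25.0, diagram).primary == "pure-drug"

    def test_boundary_tie_break(self, diagram):
        x = 0.66
        tsol = diagram.solubility_at(x)
        lab = classify_state(x, tsol, diagram)
        assert lab.primary == "boundary"
        assert set(lab.boundary_between) == {"supersaturated-liquid",
                                             "undersaturated-liquid"}

    def test_classifier_partitions_the_plane(self, diagram):
        # away from curves, every point gets exactly one primary label
        primaries = {"undersaturated-liquid", "supersaturated-liquid", "glassy"}
        rng = np.random.default_rng(5)
        for _ in range(60):
            x = rng.uniform(0.05, 0.95)
            t = rng.uniform(0.0, 180.0)
            lab = classify_state(x, t, diagram)
            if lab.primary == "boundary":
                continue
            assert lab.primary in primaries
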