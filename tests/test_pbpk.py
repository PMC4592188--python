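"""Whole-body PBPK model: distribution, absorption, simulation invariants."""

import numpy as np
import pytest

from bayespbpk import pbpk
from bayespbpk.pbpk import (
    PLASMA_COMPOSITION,
    CompoundProperties,
    DoseEvent,
    InvalidPhysiologyError,
    PhysiologyVector,
    absorption_submodel,
    build_ode_rhs,
    build_system_matrix,
    compute_partition_coefficients,
    default_graph,
    reduced_graph,
    simulate_pk,
    theophylline,
)

TIMES = np.array([0.25, 0.5, 1.0, 2.0, 3.5, 5.0, 7.0, 9.0, 12.0, 24.0, 36.0])


def mean_physiology(model):
    theta = model.layout.unpack(model.initial_state())[0]
    return model.physiology(theta[0])


# --------------------------------------------------------------------------
# Partition coefficients
# --------------------------------------------------------------------------


class TestPartitionCoefficients:
    def test_identity_tissue_has_unit_kp(self):
        comp = {"plasma_like": PLASMA_COMPOSITION}
        for fu in (0.2, 0.6, 1.0):
            kp = compute_partition_coefficients(
                theophylline(fraction_unbound_plasma=fu), None,
                composition=comp)
            assert kp["plasma_like"] == pytest.approx(1.0, rel=1e-12)

    def test_hydrophilic_limit_pure_water_tissue(self):
        # lipophilicity -> -inf, no protein binding: Kp -> water ratio
        comp = {"watery": (0.50, 0.0, 0.0)}
        c = CompoundProperties(molecular_weight=100.0, lipophilicity=-30.0,
                               fraction_unbound_plasma=1.0)
        kp = compute_partition_coefficients(c, None, composition=comp)
        assert kp["watery"] == pytest.approx(0.50 / PLASMA_COMPOSITION[0],
                                             rel=1e-9)

    def test_matches_hand_evaluated_formula(self):
        # independent hand evaluation of the documented closed form for
        # logP = 0, fu = 0.6 on three organs of the packaged composition
        fu = 0.6
        w_p, l_p, p_p = PLASMA_COMPOSITION
        lq = 1.0  # 10**0, neutral compound
        B = (1 - fu) / fu * (w_p + lq * l_p) / p_p
        a_p = w_p + lq * l_p + B * p_p
        expected = {}
        for organ in ("muscle", "fat", "liver"):
            w, l, p = pbpk.TISSUE_COMPOSITION[organ]
            expected[organ] = (w + lq * l + B * p) / a_p
        c = CompoundProperties(molecular_weight=180.0, lipophilicity=0.0,
                               fraction_unbound_plasma=0.6)
        kp = compute_partition_coefficients(c, None)
        for organ, val in expected.items():
            assert kp[organ] == pytest.approx(val, rel=1e-12)
        assert all(v > 0 for v in kp.values())

    def test_invalid_composition_raises(self):
        with pytest.raises(InvalidPhysiologyError):
            compute_partition_coefficients(
                theophylline(), None, composition={"bad": (-0.1, 0.0, 0.0)})


# --------------------------------------------------------------------------
# ODE system
# --------------------------------------------------------------------------


class TestOdeSystem:
    def test_zero_state_zero_derivatives(self, model):
        rhs = build_ode_rhs(default_graph(), mean_physiology(model),
                            theophylline())
        assert np.all(rhs(0.0, np.zeros(default_graph().n_states)) == 0)

    def test_columns_sum_to_zero_mass_conserving(self, model):
        A = build_system_matrix(default_graph(), mean_physiology(model),
                                theophylline())
        assert np.abs(A.sum(axis=0)).max() < 1e-14

    def test_body_amount_constant_without_clearance(self, model):
        # drop both clearance routes; after absorption completes the amount
        # in the body (everything except lumen/unabsorbed) stays constant
        phys = mean_physiology(model)
        vals = {k: v for k, v in phys.values.items()
                if k not in ("specCL", "specTS")}
        vals["intP"] = 1e-2  # fast absorption
        phys = PhysiologyVector(vals)
        res = simulate_pk(phys, theophylline(), DoseEvent(320.0),
                          np.array([48.0, 96.0, 192.0]))
        g = default_graph()
        lumen = [g.index("stomach_lumen"), g.index("unabsorbed")] + \
            [g.index(f"gut_lumen_{i+1}") for i in range(g.n_gut_segments)]
        body = np.delete(res.amounts, lumen, axis=1).sum(axis=1)
        assert np.all(np.abs(np.diff(body)) < 1e-6 * body[0])

    def test_two_compartment_reduction_matches_closed_form(self):
        # one well-stirred organ exchanging with the venous pool: the exact
        # 2x2 linear solution is known in closed form
        vm, q, hct, kp_target = 29.0, 1.05, 0.45, None
        phys = PhysiologyVector({"volume_muscle": vm, "flow_muscle": q,
                                 "hematocrit": hct})
        comp = theophylline()
        kp = compute_partition_coefficients(comp, phys)["muscle"]
        graph = reduced_graph(["muscle"])
        dose = 100.0
        t_h = np.array([0.1, 0.5, 1.0, 4.0, 12.0])
        res = simulate_pk(phys, comp, DoseEvent(dose), t_h, graph=graph)
        v_ven = pbpk.BLOOD_POOL_PLASMA_VOLUMES["venous"]
        k1 = q * (1 - hct) / v_ven          # venous -> organ
        k2 = q * (1 - hct) / (kp * vm)      # organ -> venous
        lam = k1 + k2
        t = t_h * 60.0
        organ = dose * k1 / lam * (1 - np.exp(-lam * t))
        ven = dose * (k2 + k1 * np.exp(-lam * t)) / lam
        np.testing.assert_allclose(res.amounts[:, graph.index("muscle")],
                                   organ, rtol=1e-6)
        np.testing.assert_allclose(res.venous_plasma_conc, ven / v_ven,
                                   rtol=1e-6)


# --------------------------------------------------------------------------
# Absorption submodel
# --------------------------------------------------------------------------


class TestAbsorption:
    def test_rate_constants(self):
        k_ge, k_t, k_abs = absorption_submodel(20.0, 150.0, 2e-6)
        assert k_ge == pytest.approx(1 / 20.0)
        assert k_t == pytest.approx(5 / 150.0)
        assert k_abs == pytest.approx(2e-6 * pbpk.SEGMENT_SA_OVER_V)

    def test_zero_permeability_nothing_absorbed(self, model):
        phys = dict(mean_physiology(model).values)
        phys["intP"] = 1e-300
        res = simulate_pk(PhysiologyVector(phys), theophylline(),
                          DoseEvent(320.0), np.array([200.0]))
        g = default_graph()
        assert res.amounts[-1, g.index("unabsorbed")] == pytest.approx(
            320.0, rel=1e-6)
        assert res.venous_plasma_conc[-1] < 1e-6

    def test_infinite_permeability_fully_absorbed(self, model):
        phys = dict(mean_physiology(model).values)
        phys["intP"] = 1e3
        res = simulate_pk(PhysiologyVector(phys), theophylline(),
                          DoseEvent(320.0), np.array([100.0]))
        g = default_graph()
        assert res.amounts[-1, g.index("unabsorbed")] < 1e-9 * 320.0

    def test_one_segment_competing_rates_analytic(self, model):
        # single intestinal segment: fraction escaping absorption is
        # k_transit / (k_abs + k_transit), a textbook competing-rates result
        phys = dict(mean_physiology(model).values)
        graph = pbpk.CompartmentGraph(n_gut_segments=1)
        k_abs = phys["intP"] * pbpk.SEGMENT_SA_OVER_V
        k_t = 1.0 / phys["ITT"]
        res = simulate_pk(PhysiologyVector(phys), theophylline(),
                          DoseEvent(100.0), np.array([2000.0]), graph=graph)
        unabs = res.amounts[-1, graph.index("unabsorbed")]
        assert unabs / 100.0 == pytest.approx(k_t / (k_abs + k_t), rel=1e-6)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(InvalidPhysiologyError):
            absorption_submodel(0.0, 150.0, 1e-6)


# --------------------------------------------------------------------------
# Simulation invariants
# --------------------------------------------------------------------------


class TestSimulation:
    def test_zero_dose_all_zero(self, model):
        res = simulate_pk(mean_physiology(model), theophylline(),
                          DoseEvent(0.0), TIMES)
        assert np.all(res.venous_plasma_conc == 0)
        assert np.all(res.urinary_fraction == 0)

    def test_dose_linearity(self, model):
        phys = mean_physiology(model)
        r1 = simulate_pk(phys, theophylline(), DoseEvent(160.0), TIMES)
        r2 = simulate_pk(phys, theophylline(), DoseEvent(320.0), TIMES)
        np.testing.assert_allclose(2 * r1.venous_plasma_conc,
                                   r2.venous_plasma_conc, rtol=1e-6)

    def test_mass_balance_on_random_draws(self, model, rng):
        # dose = body + lumen + eliminated + unabsorbed at every time point
        mu, sd = model.scaled_moments(model.priors.M_mu, model.priors.S_mu)
        for _ in range(5):
            x = np.clip(mu[0] + 0.5 * sd[0] * rng.standard_normal(len(mu[0])),
                        model.priors.x_lower, model.priors.x_upper)
            res = simulate_pk(model.physiology(x), theophylline(),
                              DoseEvent(320.0), TIMES)
            assert np.all(np.abs(res.total_mass_balance - 320.0)
                          < 1e-6 * 320.0)

    def test_renal_only_urinary_fraction_approaches_one(self, model):
        phys = {k: v for k, v in mean_physiology(model).values.items()
                if k != "specCL"}
        phys["intP"] = 1.0  # absorb essentially everything
        res = simulate_pk(PhysiologyVector(phys), theophylline(),
                          DoseEvent(320.0), np.array([50000.0]))
        assert res.urinary_fraction[-1] == pytest.approx(1.0, abs=1e-6)

    def test_urinary_fraction_monotone_and_bounded(self, model):
        res = simulate_pk(mean_physiology(model), theophylline(),
                          DoseEvent(320.0), TIMES)
        assert np.all(np.diff(res.urinary_fraction) >= -1e-12)
        assert res.urinary_fraction[-1] <= 1.0
        assert np.all(res.venous_plasma_conc >= 0)

    def test_monotone_clearance_never_increases_auc(self, model):
        phys = dict(mean_physiology(model).values)
        grid_t = np.linspace(0.1, 48.0, 200)
        aucs = []
        for mult in (1.0, 2.0, 5.0):
            p = dict(phys)
            p["specCL"] = phys["specCL"] * mult
            res = simulate_pk(PhysiologyVector(p), theophylline(),
                              DoseEvent(320.0), grid_t)
            aucs.append(np.trapezoid(res.venous_plasma_conc, grid_t))
        assert aucs[0] > aucs[1] > aucs[2]

    def test_bdf_agrees_with_expm(self, model):
        phys = mean_physiology(model)
        r1 = simulate_pk(phys, theophylline(), DoseEvent(320.0), TIMES)
        r2 = simulate_pk(phys, theophylline(), DoseEvent(320.0), TIMES,
                         method="bdf", rtol=1e-10, atol=1e-12)
        np.testing.assert_allclose(r1.venous_plasma_conc,
                                   r2.venous_plasma_conc, rtol=1e-5)

    def test_unsorted_grid_rejected(self, model):
        with pytest.raises(ValueError):
            simulate_pk(mean_physiology(model), theophylline(),
                        DoseEvent(1.0), np.array([2.0, 1.0]))


class TestDomainTypes:
    def test_compound_validation(self):
        with pytest.raises(ValueError):
            CompoundProperties(molecular_weight=-1, lipophilicity=0,
                               fraction_unbound_plasma=0.5)
        with pytest.raises(ValueError):
            CompoundProperties(molecular_weight=100, lipophilicity=0,
                               fraction_unbound_plasma=1.5)

    def test_physiology_positivity(self):
        with pytest.raises(InvalidPhysiologyError):
            PhysiologyVector({"volume_liver": -2.0})

    def test_constraint_check(self):
        p = PhysiologyVector({"volume_a": 1.0, "volume_b": 2.0})
        p.check_constraint(3.0)
        with pytest.raises(InvalidPhysiologyError):
            p.check_constraint(3.5)

    def test_dose_validation(self):
        with pytest.raises(ValueError):
            DoseEvent(-1.0)
        with pytest.raises(ValueError):
            DoseEvent(1.0, route="iv")

    def test_graph_has_22_circuit_compartments(self):
        g = default_graph()
        circuit = [n for n in g.state_names
                   if not n.startswith(("stomach_lumen", "gut_lumen"))
                   and n not in ("metabolized", "urine", "unabsorbed")]
        assert len(circuit) == 22
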