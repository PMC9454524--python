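"""Coupled drug transport: kinetics oracles, feedback relations, invariants."""


import numpy as np
import pytest
from scipy.integrate import solve_ivp

from cedsim import flow as F, grid as G, transport as T

from conftest import drug_without_diffusion, make_uniform_tumor, zero_flow


class TestOmega:
    def test_reduces_to_ecs_fraction_without_partitioning(self):
        assert T.omega_field(0.4, 0.5, 0.1, K_BC=0, H_IE=0, H_CE=0) == pytest.approx(0.4)

    def test_full_intracellular_partitioning_adds_ics(self):
        assert T.omega_field(0.4, 0.5, 0.1, K_BC=0, H_IE=1, H_CE=0) == pytest.approx(0.9)

    def test_default_constants_arithmetic(self):
        d = T.DrugLibrary()
        w = T.omega_field(0.4, 0.45, 0.0693, d.K_BC, d.H_IE, d.H_CE)
        assert w == pytest.approx(1.004, abs=1e-3)

    def test_equilibrium_compartment_relations(self):
        d = T.DrugLibrary()
        shape = (2, 2, 2)
        st = T.TransportState(
            C_LP=np.zeros(shape), C_FD=np.full(shape, 2e-4),
            C_AA=np.zeros(shape), phi=np.ones(shape),
            epsBL=np.full(shape, 0.02), epsECS=np.full(shape, 0.3),
            epsCM=np.full(shape, 0.09), epsICS=np.full(shape, 0.59), t_s=0.0)
        comp = st.derived_fd_compartments(d)
        assert np.allclose(comp["C_BD_ECS"], d.K_BC * 2e-4)
        assert np.allclose(comp["C_FD_ICS"], d.H_IE * 2e-4)
        assert np.allclose(comp["C_FD_CM"], d.H_CE * 2e-4)


class TestFractionUpdate:
    def setup_method(self):
        _, self.tis = make_uniform_tumor((2, 2, 2), epsBL=0.08, epsECS=0.3)

    def test_identity_at_phi_one(self):
        eB, eE = T.update_fractions(np.ones((2, 2, 2)), self.tis)
        assert np.allclose(eB, 0.08) and np.allclose(eE, 0.3)

    def test_full_regression_moves_plasma_into_ecs(self):
        eB, eE = T.update_fractions(np.zeros((2, 2, 2)), self.tis)
        assert np.allclose(eB, 0.0) and np.allclose(eE, 0.3 + 0.08)

    def test_half_phi_quarter_plasma(self):
        eB, eE = T.update_fractions(np.full((2, 2, 2), 0.5), self.tis)
        assert np.allclose(eB, 0.02) and np.allclose(eE, 0.3 + 0.06)

    def test_closure_preserved(self):
        eB, eE = T.update_fractions(np.full((2, 2, 2), 0.7), self.tis)
        assert np.allclose(eB + eE + self.tis.epsCM + self.tis.epsICS, 1.0)

    def test_phi_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            T.update_fractions(np.full((2, 2, 2), 1.5), self.tis)


class TestPhiKinetics:
    drug = T.DrugLibrary()

    def test_unity_is_stationary_without_drug(self):
        # the natural-angiogenesis coefficients sum to zero exactly
        assert self.drug.alpha + self.drug.beta + self.drug.gamma == 0.0
        p = T.step_phi(np.array([1.0]), np.array([0.0]), self.drug, 10 * 86400.0)
        assert p[0] == pytest.approx(1.0, abs=1e-12)

    def test_recovers_toward_unity_above_unstable_root(self):
        # cubic roots at phi ~ 0.4987 and 1; growth in between
        phis = [0.75]
        for _ in range(20):
            phis.append(float(T.step_phi(np.array([phis[-1]]), np.array([0.0]),
                                         self.drug, 43200.0)[0]))
        assert np.all(np.diff(phis) > 0) and phis[-1] < 1.0 + 1e-12

    def test_matches_adaptive_ode_oracle_under_constant_drug(self):
        CA = 7.26e-5
        d = self.drug

        def f(t, y):
            return y * (d.alpha + d.beta * y + d.gamma * y**2) - d.k_a * y * CA

        oracle = solve_ivp(f, [0, 86400.0], [1.0], rtol=1e-10, atol=1e-14).y[0, -1]
        mine = T.step_phi(np.array([1.0]), np.array([CA]), d, 86400.0)[0]
        assert abs(mine - oracle) / oracle < 1e-6

    def test_exponential_decay_slope_matches_antiangiogenic_rate(self):
        CA = 7.26e-5
        ts = np.linspace(0, 86400.0, 25)
        phi = [1.0]
        for dt in np.diff(ts):
            phi.append(float(T.step_phi(np.array([phi[-1]]), np.array([CA]),
                                        self.drug, dt)[0]))
        slope = np.polyfit(ts, np.log(phi), 1)[0]
        assert abs(-slope - self.drug.k_a * CA) / (self.drug.k_a * CA) < 0.10


def _single_cell_setup(drug, regimen="liposomalTMZ"):
    g, tis = make_uniform_tumor((4, 4, 4))
    cath = G.CatheterSpec(tip_index=(0, 0, 0), has_track=False)
    reg = T.RegimenSpec(regimen=regimen, T_in_days=0.05)
    stepper = T.DrugStepper(g, tis, drug, cath, reg)
    stepper._dirichlet = {"lp": None, "fd": None, "aa": None}   # free decay
    shape = g.shape
    state = T.TransportState(
        C_LP=np.zeros(shape), C_FD=np.zeros(shape), C_AA=np.zeros(shape),
        phi=np.ones(shape), epsBL=tis.epsBL0, epsECS=tis.epsECS0,
        epsCM=tis.epsCM, epsICS=tis.epsICS, t_s=0.0)
    return g, tis, stepper, state


class TestWellMixedKinetics:
    """Isolated-cell decays against scalar ODE solutions (D=0, v=0)."""

    def test_liposome_decay_rate(self):
        drug = drug_without_diffusion()
        g, tis, stepper, state = _single_cell_setup(drug)
        state.C_LP[...] = 1e-3
        fs = zero_flow(g.shape)
        for _ in range(60):
            state = stepper.advance(state, fs, 60.0)
        k = drug.k_rel + drug.lp.P_TV_tumor * 2.0e4    # k_rel + k_LP,b
        expected = 1e-3 * np.exp(-k * 3600.0)
        assert abs(state.C_LP[1, 1, 1] - expected) / expected < 1e-4

    def test_release_chain_matches_two_compartment_solution(self):
        drug = drug_without_diffusion()
        g, tis, stepper, state = _single_cell_setup(drug)
        state.C_LP[...] = 1e-3
        fs = zero_flow(g.shape)
        for _ in range(60):
            state = stepper.advance(state, fs, 60.0)
        eE, eI, eC = 0.4, tis.epsICS[0, 0, 0], tis.epsCM[0, 0, 0]
        om = T.omega_field(eE, eI, eC, drug.K_BC, drug.H_IE, drug.H_CE)
        k1 = drug.k_rel + drug.lp.P_TV_tumor * 2e4
        sfd = eE * drug.fd.P_TV_tumor * 2e4 + (eE + eI * drug.H_IE) * drug.fd.k_e
        r2 = sfd / om
        t = 3600.0
        w = drug.k_rel * eE * 1e-3 * (np.exp(-k1 * t) - np.exp(-r2 * t)) / (r2 - k1)
        assert abs(state.C_FD[1, 1, 1] - w / om) / (w / om) < 1e-4

    def test_antiangiogenic_elimination(self):
        drug = drug_without_diffusion()
        g, tis, stepper, state = _single_cell_setup(drug)
        state.C_AA[...] = 1e-4
        fs = zero_flow(g.shape)
        for _ in range(30):
            state = stepper.advance(state, fs, 120.0)
        expected = 1e-4 * np.exp(-drug.aa.k_e * 3600.0)
        assert abs(state.C_AA[2, 2, 2] - expected) / expected < 1e-4

    def test_drainage_scales_linearly_with_phi(self):
        drug = drug_without_diffusion()
        results = {}
        for phi_val in (1.0, 0.5):
            g, tis, stepper, state = _single_cell_setup(drug)
            state.phi[...] = phi_val
            state.C_LP[...] = 1e-3
            fs = zero_flow(g.shape)
            state = stepper.advance(state, fs, 600.0)
            led = stepper.ledgers["lp"]
            results[phi_val] = led.drained / (led.drained + led.released_out)
        k_b_full = drug.lp.P_TV_tumor * 2.0e4
        frac = lambda kb: kb / (kb + drug.k_rel)
        assert results[1.0] == pytest.approx(frac(k_b_full), rel=1e-9)
        assert results[0.5] == pytest.approx(frac(0.5 * k_b_full), rel=1e-9)


class TestRegimenSimulation:
    def test_zero_duration_returns_preinfusion_state_only(self, default_phantom):
        phm = default_phantom
        cath = G.CatheterSpec(tip_index=tuple(np.array(phm.grid.n) // 2))
        reg = T.RegimenSpec(regimen="plainTMZ", T_in_days=0.0)
        traj = T.simulate_regimen(phm.grid, phm.tissue, cath, reg)
        assert len(traj.times_s) == 1 and traj.times_s[0] == 0.0
        assert traj.preinfusion_flow is not None

    def test_short_run_budget_and_invariants(self):
        g, tis = make_uniform_tumor((10, 10, 10), h=(2.0, 2.0, 2.0))
        cath = G.CatheterSpec(tip_index=(5, 5, 4))
        reg = T.RegimenSpec(regimen="liposomalTMZ+BEV", T_in_days=0.25)
        traj = T.simulate_regimen(g, tis, cath, reg)
        assert max(traj.budget_closure.values()) < 5e-3
        t, final = traj.snapshots[-1]
        # infused species never exceed their inlet concentrations
        assert final.C_LP.max() <= reg.C_in_tmz_M * (1 + 1e-9)
        assert final.C_AA.max() <= reg.C_in_bev_M * (1 + 1e-9)
        assert final.C_FD.min() >= 0.0
        # vascular feedback consistency: epsBL/epsBL0 = phi^2
        act = g.tissue_mask
        assert np.allclose(final.epsBL[act],
                           final.phi[act] ** 2 * tis.epsBL0[act], atol=1e-12)

    def test_phi_stationary_without_antiangiogenic_drug(self):
        g, tis = make_uniform_tumor((8, 8, 8), h=(2.0, 2.0, 2.0))
        cath = G.CatheterSpec(tip_index=(4, 4, 3))
        reg = T.RegimenSpec(regimen="plainTMZ", T_in_days=0.1)
        traj = T.simulate_regimen(g, tis, cath, reg)
        _, final = traj.snapshots[-1]
        act = g.tissue_mask & ~cath.blocked_mask(g)
        assert np.all(final.phi[act] == 1.0)

    def test_homogeneous_run_is_radially_symmetric(self):
        g, tis = make_uniform_tumor((11, 11, 11), h=(2.0, 2.0, 2.0))
        cath = G.CatheterSpec(tip_index=(5, 5, 5), has_track=False)
        reg = T.RegimenSpec(regimen="plainTMZ", T_in_days=0.25)
        traj = T.simulate_regimen(g, tis, cath, reg)
        _, final = traj.snapshots[-1]
        c = final.C_FD
        peak = c.max()
        for ax in range(3):
            assert np.max(np.abs(c - np.flip(c, axis=ax))) < 0.02 * peak

    def test_unknown_regimen_rejected(self):
        with pytest.raises(ValueError, match="regimen"):
            T.RegimenSpec(regimen="bolus")
        with pytest.raises(ValueError):
            T.RegimenSpec(R_in_uL_min=20.0)
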