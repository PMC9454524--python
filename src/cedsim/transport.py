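"""Coupled drug transport with antiangiogenic feedback.

Three species move through the interstitium on the Darcy velocity field:

* liposome-encapsulated cytotoxic drug (LP), which releases free drug at a
  first-order rate and leaks to the blood through the vessel wall;
* released free cytotoxic drug (FD), which binds plasma proteins (K_BC),
  partitions into cell membrane and interior (H_CE, H_IE), is eliminated by
  degradation/bioreaction and drained to the blood;
* antiangiogenic drug (AA), which drives regression of the microvasculature
  through the scaling factor phi:  dphi/dt = phi(alpha + beta*phi + gamma*phi^2)
  - k_a * phi * C_AA.

phi feeds back on the tissue: the plasma fraction shrinks as phi^2 (vessel
radii contract), the freed volume joins the extracellular space, the vascular
surface density S/V scales with phi, and the flow problem is re-solved as the
Starling source changes.

Each species PDE is advanced in the conserved variable u = epsECS*C with a
flux-form finite-volume step: harmonic-mean face diffusion, first-order
upwind advection on the stored face velocities, and pointwise-implicit linear
sinks.  Because div v = F_BL discretely, the flux-form advection reproduces
the non-conservative v.grad form plus the F_BL dilution sink of the
continuum equations while closing the discrete mass budget to roundoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .dce import TissueProperties
from .flow import FlowState, FluidProperties, VascularProperties, solve_flow
from .grid import TUMOR, CatheterSpec, StructuredGrid

# ----------------------------------------------------------- drug library

@dataclass
class DrugParams:
    """Per-species transport/pharmacology record (tumor/normal region values)."""

    name: str
    D_tumor: float              # diffusivity in tissue ECS, m^2/s
    D_normal: float
    P_TV_tumor: float = 0.0     # transvascular permeability, m/s
    P_TV_normal: float = 0.0
    k_e: float = 0.0            # elimination rate, 1/s
    MW: float = 0.0


@dataclass
class DrugLibrary:
    """Defaults: bevacizumab (AA), TMZ-loaded liposome (LP), free temozolomide (FD)."""

    aa: DrugParams = field(default_factory=lambda: DrugParams(
        "bevacizumab", D_tumor=3.2e-13, D_normal=4.9e-14, k_e=1.2e-5, MW=1.49e5))
    lp: DrugParams = field(default_factory=lambda: DrugParams(
        "liposomal-TMZ", D_tumor=1.5e-13, D_normal=3.2e-14,
        P_TV_tumor=5.8e-8, P_TV_normal=0.0))
    fd: DrugParams = field(default_factory=lambda: DrugParams(
        "temozolomide", D_tumor=7.2e-10, D_normal=3.4e-10,
        P_TV_tumor=8.0e-8, P_TV_normal=4.3e-8, k_e=1.1e-4, MW=1.94e2))
    k_rel: float = 6.4e-4       # liposome drug-release rate, 1/s
    K_BC: float = 0.18          # free-drug protein binding constant
    H_CE: float = 1.5e-2        # cell-membrane/ECS partition coefficient
    H_IE: float = 1.0           # intracellular/ECS partition coefficient
    k_a: float = 1.12           # antiangiogenic rate, 1/(M s)
    LD90_M: float = 3.9e-5      # free-drug dose killing 90% of tumor cells
    alpha: float = -1.85e-6     # natural-angiogenesis cubic coefficients, 1/s
    beta: float = 5.56e-6
    gamma: float = -3.71e-6


@dataclass
class RegimenSpec:
    """Infusion regimen: which species enter the catheter and at what concentration."""

    regimen: str = "liposomalTMZ+BEV"
    R_in_uL_min: float = 3.0
    T_in_days: float = 3.0
    C_in_tmz_M: float = 5.15e-3
    C_in_bev_M: float = 7.26e-5

    _KNOWN = ("plainTMZ", "plainTMZ+BEV", "liposomalTMZ", "liposomalTMZ+BEV")

    def __post_init__(self):
        if self.regimen not in self._KNOWN:
            raise ValueError(f"unknown regimen {self.regimen!r}; choose from {self._KNOWN}")
        if not (0.0 < self.R_in_uL_min <= 10.0):
            raise ValueError("infusion rate must lie in (0, 10] uL/min")
        if self.C_in_tmz_M < 0 or self.C_in_bev_M < 0 or self.T_in_days < 0:
            raise ValueError("concentrations and duration must be nonnegative")

    @property
    def infuses_liposome(self) -> bool:
        return self.regimen.startswith("liposomal")

    @property
    def infuses_free_drug(self) -> bool:
        return self.regimen.startswith("plain")

    @property
    def infuses_bev(self) -> bool:
        return self.regimen.endswith("+BEV")

    @property
    def Q_in_m3s(self) -> float:
        return self.R_in_uL_min * 1e-9 / 60.0

    @property
    def T_in_s(self) -> float:
        return self.T_in_days * 86400.0


@dataclass
class Numerics:
    dt_max_s: float = 60.0
    phi_flow_threshold: float = 0.01   # re-solve flow when max|dphi| exceeds this
    cfl_safety: float = 0.8
    snapshot_interval_s: float = 6.0 * 3600.0
    flow_rtol: float = 1e-10


@dataclass
class TransportState:
    """Concentrations (M, per ECS volume), vascular scaling and fractions at time t."""

    C_LP: np.ndarray
    C_FD: np.ndarray
    C_AA: np.ndarray
    phi: np.ndarray
    epsBL: np.ndarray
    epsECS: np.ndarray
    epsCM: np.ndarray
    epsICS: np.ndarray
    t_s: float

    def derived_fd_compartments(self, drug: DrugLibrary):
        """Bound and partitioned free-drug concentrations (equilibrium relations)."""
        return {"C_BD_ECS": drug.K_BC * self.C_FD,
                "C_FD_ICS": drug.H_IE * self.C_FD,
                "C_FD_CM": drug.H_CE * self.C_FD,
                "C_BD_ICS": drug.K_BC * drug.H_IE * self.C_FD}


# ------------------------------------------------------- pointwise kinetics

def omega_field(epsECS, epsICS, epsCM, K_BC, H_IE, H_CE):
    """Free-drug effective capacity omega = eE(1+K) + eI*HIE*(1+K) + eC*HCE."""
    return (np.asarray(epsECS) * (1.0 + K_BC)
            + np.asarray(epsICS) * H_IE * (1.0 + K_BC)
            + np.asarray(epsCM) * H_CE)


def update_fractions(phi, tissue: TissueProperties):
    """Vascular regression reshapes the fractions: eBL = phi^2 * eBL0, the freed
    volume joins the ECS, cell membrane and interior stay fixed."""
    phi = np.asarray(phi)
    if np.any(phi < 0) or np.any(phi > 1 + 1e-12):
        raise ValueError("phi must lie in [0, 1]")
    epsBL = phi ** 2 * tissue.epsBL0
    epsECS = 1.0 - epsBL - tissue.epsCM - tissue.epsICS
    # exterior voxels are all-zero and must stay so
    outside = (tissue.epsBL0 + tissue.epsECS0 + tissue.epsCM + tissue.epsICS) < 0.5
    epsECS = np.where(outside, 0.0, epsECS)
    if np.any(epsECS < -1e-12):
        raise ValueError("fraction update produced negative epsECS")
    return epsBL, np.clip(epsECS, 0.0, None)


def step_phi(phi, C_AA, drug: DrugLibrary, dt_s, rate_cap=0.05):
    """Advance dphi/dt = phi(alpha + beta phi + gamma phi^2) - k_a phi C_AA.

    Vectorized classical RK4 with sub-steps sized so the fastest local rate
    advances at most ``rate_cap`` per sub-step (keeps the integration within
    ~1e-6 of an adaptive ODE solution over multi-day horizons).  C_AA is held
    constant across the step; the result is clamped to [0, 1].
    """
    if dt_s <= 0:
        raise ValueError("dt must be positive")
    phi = np.asarray(phi, dtype=float)
    C = np.asarray(C_AA, dtype=float)
    a, b, g, ka = drug.alpha, drug.beta, drug.gamma, drug.k_a

    def f(p):
        return p * (a + b * p + g * p * p) - ka * p * C

    kmax = abs(a) + abs(b) + abs(g) + ka * float(np.max(C)) if C.size else abs(a)
    n = max(1, int(np.ceil(dt_s * kmax / rate_cap)))
    h = dt_s / n
    p = phi.copy()
    for _ in range(n):
        k1 = f(p)
        k2 = f(p + 0.5 * h * k1)
        k3 = f(p + 0.5 * h * k2)
        k4 = f(p + h * k3)
        p = p + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
    return np.clip(p, 0.0, 1.0)


# ----------------------------------------------------------- FV machinery

class _SpeciesOps:
    """Precomputed per-species finite-volume coefficients on the active mask."""

    def __init__(self, grid: StructuredGrid, act: np.ndarray, drug: DrugParams):
        self.D = np.where(act,
                          np.where(grid.region == TUMOR, drug.D_tumor, drug.D_normal),
                          0.0)
        h = grid.h_mm * 1e-3
        self.Td = []   # face diffusion transmissibility / V  -> units 1/s per u-difference
        V = float(np.prod(h))
        for ax in range(3):
            shp = list(grid.shape)
            shp[ax] += 1
            Td = np.zeros(shp)
            sl_lo = [slice(None)] * 3
            sl_hi = [slice(None)] * 3
            sl_lo[ax] = slice(0, grid.shape[ax] - 1)
            sl_hi[ax] = slice(1, grid.shape[ax])
            D1 = self.D[tuple(sl_lo)]
            D2 = self.D[tuple(sl_hi)]
            Dh = np.where(D1 + D2 > 0, 2.0 * D1 * D2 / np.where(D1 + D2 > 0, D1 + D2, 1.0), 0.0)
            sl_face = [slice(None)] * 3
            sl_face[ax] = slice(1, grid.shape[ax])
            # stored as a rate (1/s): flux = -Td * (uR - uL) * V_cell
            Td[tuple(sl_face)] = Dh / h[ax] ** 2
            self.Td.append(Td)   # boundary faces stay 0: zero diffusive flux
        self.V = V
        self.h = h


def _face_fluxes(u, v_face, Td, h, V):
    """Advective (upwind) + diffusive face fluxes (m^3-scaled, per axis).

    Returns a list of flux arrays (units: u * m^3/s) with the +axis sign
    convention; boundary faces see a zero-concentration ghost so inflow
    carries nothing and outflow upwinds the interior cell.
    """
    fluxes = []
    for ax in range(3):
        v = v_face[ax]
        A = V / h[ax]
        pad = [(0, 0)] * 3
        pad[ax] = (1, 1)
        up = np.pad(u, pad, mode="constant")           # ghost u=0
        sl_l = [slice(None)] * 3
        sl_r = [slice(None)] * 3
        sl_l[ax] = slice(0, u.shape[ax] + 1)
        sl_r[ax] = slice(1, u.shape[ax] + 2)
        uL = up[tuple(sl_l)]
        uR = up[tuple(sl_r)]
        adv = A * (np.maximum(v, 0.0) * uL + np.minimum(v, 0.0) * uR)
        diff = -Td[ax] * (uR - uL) * V                 # Td already / V
        fluxes.append(adv + diff)
    return fluxes


def _divergence(fluxes, V):
    out = None
    for ax, F in enumerate(fluxes):
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[ax] = slice(0, F.shape[ax] - 1)
        sl_hi[ax] = slice(1, F.shape[ax])
        d = (F[tuple(sl_hi)] - F[tuple(sl_lo)]) / V
        out = d if out is None else out + d
    return out


def _boundary_outflux(fluxes):
    """Net mass flow rate out through the domain boundary (u * m^3/s)."""
    tot = 0.0
    for ax, F in enumerate(fluxes):
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[ax] = 0
        sl_hi[ax] = F.shape[ax] - 1
        tot += float(np.sum(F[tuple(sl_hi)]) - np.sum(F[tuple(sl_lo)]))
    return tot


@dataclass
class MassLedger:
    """Cumulative per-species mass budget (moles); excludes the Dirichlet tip cell."""

    stored0: float = 0.0
    infused: float = 0.0
    outflow: float = 0.0
    drained: float = 0.0
    eliminated: float = 0.0
    released_out: float = 0.0   # LP only: mass converted to free drug
    released_in: float = 0.0    # FD only: mass received from liposomes

    def closure_error(self, stored_now: float) -> float:
        rhs = (self.stored0 + self.infused + self.released_in
               - self.outflow - self.drained - self.eliminated - self.released_out)
        scale = max(abs(self.infused) + abs(self.released_in) + abs(stored_now), 1e-300)
        return abs(stored_now - rhs) / scale


class DrugStepper:
    """Advances the three-species system on a fixed grid and velocity field."""

    def __init__(self, grid: StructuredGrid, tissue: TissueProperties,
                 drug: DrugLibrary, catheter: CatheterSpec,
                 regimen: RegimenSpec, numerics: Numerics | None = None):
        self.grid = grid
        self.tissue = tissue
        self.drug = drug
        self.catheter = catheter
        self.regimen = regimen
        self.num = numerics or Numerics()
        self.act = grid.tissue_mask & ~catheter.blocked_mask(grid)
        self.tip = catheter.validate(grid)
        self.ops = {"lp": _SpeciesOps(grid, self.act, drug.lp),
                    "fd": _SpeciesOps(grid, self.act, drug.fd),
                    "aa": _SpeciesOps(grid, self.act, drug.aa)}
        self.V = self.ops["lp"].V
        self.h = self.ops["lp"].h
        self.P_TV = {s: np.where(grid.region == TUMOR, d.P_TV_tumor, d.P_TV_normal)
                     for s, d in (("lp", drug.lp), ("fd", drug.fd))}
        self.ledgers = {"lp": MassLedger(), "fd": MassLedger(), "aa": MassLedger()}
        self.not_tip = np.ones(grid.shape, dtype=bool)
        self.not_tip[self.tip] = False
        self._dirichlet = {
            "lp": regimen.C_in_tmz_M if regimen.infuses_liposome else None,
            "fd": regimen.C_in_tmz_M if regimen.infuses_free_drug else None,
            "aa": regimen.C_in_bev_M if regimen.infuses_bev else None,
        }

    # -- helpers ---------------------------------------------------------
    def capacity(self, species, epsECS, epsICS=None, epsCM=None):
        if species == "fd":
            return omega_field(epsECS,
                               self.tissue.epsICS if epsICS is None else epsICS,
                               self.tissue.epsCM if epsCM is None else epsCM,
                               self.drug.K_BC, self.drug.H_IE, self.drug.H_CE)
        return np.asarray(epsECS)

    def budget_mask(self, species):
        """Cells whose content the ledger tracks: the Dirichlet tip is external."""
        if self._dirichlet[species] is not None:
            return self.act & self.not_tip
        return self.act

    def stored_mass(self, species, C, epsECS):
        m = self.capacity(species, epsECS)
        return float(np.sum((m * C * self.V)[self.budget_mask(species)]))

    def stable_dt(self, v_face):
        """Positivity-preserving explicit time-step bound, tightest species."""
        coef = None
        for s, ops in self.ops.items():
            c = np.zeros(self.grid.shape)
            for ax in range(3):
                v = v_face[ax]
                sl_lo = [slice(None)] * 3
                sl_hi = [slice(None)] * 3
                sl_lo[ax] = slice(0, self.grid.shape[ax])
                sl_hi[ax] = slice(1, self.grid.shape[ax] + 1)
                v_in = v[tuple(sl_lo)]
                v_out = v[tuple(sl_hi)]
                c += (np.maximum(v_out, 0.0) - np.minimum(v_in, 0.0)) / self.h[ax]
                Td = ops.Td[ax]
                c += Td[tuple(sl_lo)] + Td[tuple(sl_hi)]
            cmax = float(c[self.act].max()) if np.any(self.act) else 0.0
            coef = cmax if coef is None else max(coef, cmax)
        if coef <= 0:
            return np.inf
        return self.num.cfl_safety / coef

    def apply_dirichlet(self, state: TransportState):
        for s, val in self._dirichlet.items():
            if val is None:
                continue
            {"lp": state.C_LP, "fd": state.C_FD, "aa": state.C_AA}[s][self.tip] = val

    # -- the step --------------------------------------------------------
    def advance(self, state: TransportState, flowstate: FlowState, dt_s,
                eps_prev=None) -> TransportState:
        """One macro step of the three coupled species PDEs.

        ``eps_prev`` is the epsECS field at the start of the step when phi
        moved since the previous call; capacities then use the conservative
        pairing (m^{n+1} C^{n+1} - m^n C^n)/dt so the slow fraction drift
        stays mass-consistent.
        """
        if dt_s <= 0:
            raise ValueError("dt must be positive")
        num_sub = max(1, int(np.ceil(dt_s / min(self.stable_dt(flowstate.v_face),
                                                self.num.dt_max_s))))
        h_s = dt_s / num_sub

        phi = state.phi
        epsECS = state.epsECS
        eE_prev = epsECS if eps_prev is None else eps_prev
        C = {"lp": state.C_LP.copy(), "fd": state.C_FD.copy(), "aa": state.C_AA.copy()}

        # phi-scaled blood-drainage rates (1/s)
        sv = phi * self.tissue.sv0
        k_b = {"lp": self.P_TV["lp"] * sv, "fd": self.P_TV["fd"] * sv}
        m_fd = self.capacity("fd", epsECS)
        m_fd_prev = self.capacity("fd", eE_prev)
        eI_HIE = self.tissue.epsICS * self.drug.H_IE

        for sub in range(num_sub):
            first = sub == 0
            eE_old = eE_prev if first else epsECS
            mfd_old = m_fd_prev if first else m_fd

            u = {s: np.where(self.act, epsECS * C[s], 0.0) for s in C}
            flux = {s: _face_fluxes(u[s], flowstate.v_face, self.ops[s].Td,
                                    self.h, self.V)
                    for s in C}
            div = {s: _divergence(flux[s], self.V) for s in C}

            # explicit transport increment in capacity variables
            w_lp = eE_old * C["lp"] - h_s * div["lp"]
            w_fd = mfd_old * C["fd"] - h_s * div["fd"]
            w_aa = eE_old * C["aa"] - h_s * div["aa"]

            # reactions: exact exponential update of the linear kinetics chain
            # LP decays at k1 = k_rel + k_LP,b and feeds FD; FD decays at
            # r2 = [eE k_FD,b + (eE + eI H_IE) k_FD,e] / omega; AA decays at k_AA,e.
            k1 = self.drug.k_rel + k_b["lp"]
            E1 = np.exp(-k1 * h_s)
            g1 = np.where(k1 > 0, (1.0 - E1) / np.where(k1 > 0, k1, 1.0), h_s)
            rel_frac = np.where(k1 > 0, self.drug.k_rel / np.where(k1 > 0, k1, 1.0), 0.0)
            lp_loss = w_lp * (1.0 - E1)          # total LP mass density lost
            rel = w_lp * self.drug.k_rel * g1    # portion converted to free drug
            w_lp_new = w_lp * E1

            s_fd = epsECS * k_b["fd"] + (epsECS + eI_HIE) * self.drug.fd.k_e
            mf = np.clip(m_fd, 1e-12, None)
            r2 = np.where(self.act, s_fd / mf, 0.0)
            E2 = np.exp(-r2 * h_s)
            dk = r2 - k1
            small = np.abs(dk) < 1e-14
            src_fac = np.where(small, h_s * E1,
                               (E1 - E2) / np.where(small, 1.0, dk))
            w_fd_new = w_fd * E2 + self.drug.k_rel * w_lp * src_fac
            fd_sink = w_fd + rel - w_fd_new      # exact by mass conservation

            E3 = np.exp(-self.drug.aa.k_e * h_s)
            w_aa_new = w_aa * E3
            aa_loss = w_aa * (1.0 - E3)

            new_C = {
                "lp": np.where(self.act, np.clip(w_lp_new, 0.0, None)
                               / np.clip(epsECS, 1e-12, None), 0.0),
                "fd": np.where(self.act, np.clip(w_fd_new, 0.0, None) / mf, 0.0),
                "aa": np.where(self.act, np.clip(w_aa_new, 0.0, None)
                               / np.clip(epsECS, 1e-12, None), 0.0),
            }

            # ledger accounting (a Dirichlet tip cell is external to the budget)
            for s in C:
                led = self.ledgers[s]
                led.outflow += _boundary_outflux(flux[s]) * h_s
                if self._dirichlet[s] is not None:
                    # net flux out of the tip cell feeds the domain
                    tip_div = sum(
                        float(flux[s][ax][tuple(np.add(self.tip, np.eye(3, dtype=int)[ax]))]
                              - flux[s][ax][self.tip]) for ax in range(3))
                    led.infused += tip_div * h_s
            m_lp = self.budget_mask("lp")
            m_fdm = self.budget_mask("fd")
            m_aa = self.budget_mask("aa")
            self.ledgers["lp"].drained += float(np.sum(((lp_loss - rel) * self.V)[m_lp]))
            self.ledgers["lp"].released_out += float(np.sum((rel * self.V)[m_lp]))
            self.ledgers["fd"].released_in += float(np.sum((rel * self.V)[m_fdm]))
            sfd_safe = np.where(s_fd > 0, s_fd, 1.0)
            frac_b = np.where(s_fd > 0, epsECS * k_b["fd"] / sfd_safe, 0.0)
            self.ledgers["fd"].drained += float(np.sum((fd_sink * frac_b * self.V)[m_fdm]))
            self.ledgers["fd"].eliminated += float(np.sum(
                (fd_sink * (np.where(s_fd > 0, 1.0, 0.0) - frac_b) * self.V)[m_fdm]))
            self.ledgers["aa"].eliminated += float(np.sum((aa_loss * self.V)[m_aa]))

            for s in C:
                C[s] = new_C[s]
                if self._dirichlet[s] is not None:
                    C[s][self.tip] = self._dirichlet[s]

            if np.any(np.array([C[s].min() for s in C]) < -1e-12):
                raise RuntimeError("negative concentration beyond tolerance")

        new_state = replace(state, C_LP=C["lp"], C_FD=C["fd"], C_AA=C["aa"],
                            t_s=state.t_s + dt_s)
        return new_state


# --------------------------------------------------------------- regimen run

@dataclass
class Trajectory:
    """Time series and snapshots collected over one simulated regimen."""

    times_s: list = field(default_factory=list)
    tumor_avg_fd_M: list = field(default_factory=list)
    tumor_avg_aa_M: list = field(default_factory=list)
    tumor_avg_phi: list = field(default_factory=list)
    tumor_avg_epsBL: list = field(default_factory=list)
    tumor_avg_epsECS: list = field(default_factory=list)
    tumor_avg_FBL_s: list = field(default_factory=list)
    snapshots: list = field(default_factory=list)       # (t_s, TransportState)
    flow_snapshots: list = field(default_factory=list)  # (t_s, FlowState)
    preinfusion_flow: FlowState = None
    ledgers: dict = None
    budget_closure: dict = None


def simulate_regimen(grid: StructuredGrid, tissue: TissueProperties,
                     catheter: CatheterSpec, regimen: RegimenSpec,
                     drug: DrugLibrary | None = None,
                     fluid: FluidProperties | None = None,
                     numerics: Numerics | None = None,
                     snapshot_fields: bool = True) -> Trajectory:
    """Run one infusion regimen end to end.

    (i) pre-infusion steady flow at phi=1 (the hydraulic state before CED);
    (ii) infusion switched on at t=0: each macro step advances phi, updates
    the volume fractions, re-solves the flow when phi has moved by more than
    the coupling threshold, and advances the three drug PDEs.  Initial drug
    concentrations are zero everywhere.
    """
    drug = drug or DrugLibrary()
    numerics = numerics or Numerics()
    fluid = fluid or FluidProperties.from_regions(grid)
    vasc = VascularProperties.from_regions(grid, sv0=tissue.sv0)

    stepper = DrugStepper(grid, tissue, drug, catheter, regimen, numerics)
    tumor = grid.tumor_mask & stepper.act

    pre_flow = solve_flow(grid, fluid, vasc, phi=1.0, catheter=catheter,
                          Q_in=0.0, rtol=numerics.flow_rtol)
    traj = Trajectory(preinfusion_flow=pre_flow)

    phi = np.where(stepper.act, 1.0, 0.0)
    epsBL, epsECS = update_fractions(phi, tissue)
    state = TransportState(C_LP=np.zeros(grid.shape), C_FD=np.zeros(grid.shape),
                           C_AA=np.zeros(grid.shape), phi=phi,
                           epsBL=epsBL, epsECS=epsECS,
                           epsCM=tissue.epsCM, epsICS=tissue.epsICS, t_s=0.0)
    stepper.apply_dirichlet(state)

    flowstate = solve_flow(grid, fluid, vasc, phi=phi, catheter=catheter,
                           Q_in=regimen.Q_in_m3s, rtol=numerics.flow_rtol)
    phi_at_flow = phi.copy()

    def record(force=False):
        t = state.t_s
        traj.times_s.append(t)
        eV = state.epsECS * 1.0
        w = eV[tumor]
        wsum = float(w.sum())
        traj.tumor_avg_fd_M.append(float((state.C_FD[tumor] * w).sum() / wsum))
        traj.tumor_avg_aa_M.append(float((state.C_AA[tumor] * w).sum() / wsum))
        traj.tumor_avg_phi.append(float(state.phi[tumor].mean()))
        traj.tumor_avg_epsBL.append(float(state.epsBL[tumor].mean()))
        traj.tumor_avg_epsECS.append(float(state.epsECS[tumor].mean()))
        traj.tumor_avg_FBL_s.append(float(flowstate.F_BL[tumor].mean()))
        if snapshot_fields:
            traj.snapshots.append((t, replace(state)))
            traj.flow_snapshots.append((t, flowstate))

    # initialize stored-mass baselines (all zero fields)
    for s, C0 in (("lp", state.C_LP), ("fd", state.C_FD), ("aa", state.C_AA)):
        stepper.ledgers[s].stored0 = stepper.stored_mass(s, C0, state.epsECS)
    record()

    T = regimen.T_in_s
    next_snap = numerics.snapshot_interval_s
    t = 0.0
    has_aa = regimen.infuses_bev
    while t < T - 1e-9:
        dt = min(numerics.dt_max_s, T - t)
        eps_prev = state.epsECS
        if has_aa:
            phi_new = step_phi(state.phi, state.C_AA, drug, dt)
            phi_new = np.where(stepper.act, phi_new, 0.0)
            epsBL, epsECS = update_fractions(phi_new, tissue)
            state = replace(state, phi=phi_new, epsBL=epsBL, epsECS=epsECS)
            if float(np.max(np.abs(phi_new - phi_at_flow))) > numerics.phi_flow_threshold:
                flowstate = solve_flow(grid, fluid, vasc, phi=phi_new,
                                       catheter=catheter, Q_in=regimen.Q_in_m3s,
                                       rtol=numerics.flow_rtol)
                phi_at_flow = phi_new.copy()
        state = stepper.advance(state, flowstate, dt, eps_prev=eps_prev)
        if not np.all(np.isfinite(state.C_FD)):
            raise RuntimeError(f"non-finite concentration field at t={state.t_s:.0f}s")
        t = state.t_s
        if t >= next_snap - 1e-9 or t >= T - 1e-9:
            record()
            next_snap += numerics.snapshot_interval_s

    traj.ledgers = stepper.ledgers
    traj.budget_closure = {
        s: stepper.ledgers[s].closure_error(
            stepper.stored_mass(s, {"lp": state.C_LP, "fd": state.C_FD,
                                    "aa": state.C_AA}[s], state.epsECS))
        for s in ("lp", "fd", "aa")}
    return traj
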