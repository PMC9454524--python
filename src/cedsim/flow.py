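"""Interstitial fluid flow: quasi-steady Darcy flow with Starling transvascular exchange.

The tissue is a rigid porous medium.  At interstitial velocities (um/s) and
permeabilities (~1e-14 m^2) the Darcy drag dominates inertia and Brinkman
shear by many orders of magnitude, so the momentum balance reduces to
v = -(kappa/mu) grad p and the continuity equation div v = F_BL becomes a
single elliptic problem for the interstitial fluid pressure:

    -div( (kappa/mu) grad p ) = F_BL(p) + q_in,
    F_BL = L_BL (phi S0/V) [p_BL - p - sigma (pi_BL - pi_ISF)]

with p = 0 (gauge) on the outer boundary, no-flux at exterior/blocked cells,
and the infusion as a volumetric source in the catheter tip cell.  The
Starling term is linear in p and is folded into the matrix diagonal, so one
sparse SPD solve gives the exact quasi-steady state; the flow is re-solved
whenever the vascular scaling phi changes appreciably.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .grid import TUMOR, CatheterSpec, StructuredGrid

# Table of baseline tissue hydraulics (tumor, normal)
KAPPA_TUMOR = 6.4e-14        # m^2
KAPPA_NORMAL = 6.5e-15
MU_ISF = 7.8e-4              # Pa s
RHO_ISF = 1000.0             # kg/m^3 (unused by the reduced solver)
L_BL_TUMOR = 1.1e-12         # m/(Pa s)
L_BL_NORMAL = 1.4e-13
P_BLOOD = 4610.0             # Pa
SIGMA_TUMOR = 0.82
SIGMA_NORMAL = 0.91
PI_BLOOD = 3440.0            # Pa
PI_ISF_TUMOR = 1110.0
PI_ISF_NORMAL = 740.0


@dataclass
class FluidProperties:
    """Interstitial fluid and tissue hydraulics (per-cell permeability)."""

    kappa: np.ndarray            # m^2
    mu: float = MU_ISF
    rho: float = RHO_ISF

    @classmethod
    def from_regions(cls, grid: StructuredGrid, kappa_tumor=KAPPA_TUMOR,
                     kappa_normal=KAPPA_NORMAL, **kw):
        kappa = np.where(grid.region == TUMOR, kappa_tumor, kappa_normal)
        kappa = np.where(grid.tissue_mask, kappa, 0.0)
        return cls(kappa=kappa, **kw)


@dataclass
class VascularProperties:
    """Starling-exchange parameters; SV0 is the baseline S_BL,0/V_T field (m^-1)."""

    L_BL: np.ndarray
    SV0: np.ndarray
    sigma_BL: np.ndarray
    pi_ISF: np.ndarray
    p_BL: float = P_BLOOD
    pi_BL: float = PI_BLOOD

    @classmethod
    def from_regions(cls, grid: StructuredGrid, sv0, **kw):
        t = grid.region == TUMOR
        mk = grid.tissue_mask
        return cls(L_BL=np.where(mk, np.where(t, L_BL_TUMOR, L_BL_NORMAL), 0.0),
                   SV0=np.where(mk, sv0, 0.0),
                   sigma_BL=np.where(t, SIGMA_TUMOR, SIGMA_NORMAL),
                   pi_ISF=np.where(t, PI_ISF_TUMOR, PI_ISF_NORMAL), **kw)

    def equilibrium_pressure(self) -> np.ndarray:
        """Zero-flux pressure p_BL - sigma (pi_BL - pi_ISF), per cell."""
        return self.p_BL - self.sigma_BL * (self.pi_BL - self.pi_ISF)


@dataclass
class FlowState:
    p: np.ndarray                 # Pa, cell-centered
    v_face: tuple                 # face-normal Darcy velocities per axis (m/s)
    F_BL: np.ndarray              # transvascular volumetric source (1/s)
    balance: dict                 # discrete mass-budget report


def starling_source(p, vasc: VascularProperties, phi) -> np.ndarray:
    """Transvascular fluid gain F_BL (s^-1) by Starling's law; phi scales S/V."""
    p = np.asarray(p, dtype=float)
    return vasc.L_BL * (np.asarray(phi) * vasc.SV0) * (
        vasc.p_BL - p - vasc.sigma_BL * (vasc.pi_BL - vasc.pi_ISF))


def _active_mask(grid: StructuredGrid, catheter: CatheterSpec | None):
    act = grid.tissue_mask.copy()
    if catheter is not None:
        act &= ~catheter.blocked_mask(grid)
    return act


def solve_flow(grid: StructuredGrid, fluid: FluidProperties,
               vasc: VascularProperties, phi=1.0,
               catheter: CatheterSpec | None = None, Q_in=0.0,
               rtol=1e-10) -> FlowState:
    """Solve the Darcy--Starling pressure problem and derive face velocities.

    Q_in (m^3/s) enters the catheter tip cell as a volumetric source.
    Harmonic-mean face permeabilities; homogeneous Dirichlet pressure on the
    outer domain boundary; interior tissue--exterior and catheter faces carry
    no flux.  Returns the pressure, face velocities, the Starling source
    consistent with the solved pressure, and a discrete mass-balance report.
    """
    if Q_in < 0:
        raise ValueError("infusion rate must be nonnegative")
    act = _active_mask(grid, catheter)
    if not np.any(act):
        raise ValueError("no active tissue cells; flow problem is empty")
    nx, ny, nz = grid.shape
    hx, hy, hz = grid.h_mm * 1e-3
    h = (hx, hy, hz)
    areas = (hy * hz, hx * hz, hx * hy)
    Vc = hx * hy * hz

    idx = -np.ones(grid.shape, dtype=np.int64)
    idx[act] = np.arange(int(act.sum()))
    nun = int(act.sum())

    kmu = np.where(act, fluid.kappa, 0.0) / fluid.mu
    phi_f = np.broadcast_to(np.asarray(phi, dtype=float), grid.shape)
    b = vasc.L_BL * phi_f * vasc.SV0                         # 1/(Pa s)
    a = b * (vasc.p_BL - vasc.sigma_BL * (vasc.pi_BL - vasc.pi_ISF))

    rows, cols, vals = [], [], []
    diag = b[act] * Vc                                       # Starling linearity
    rhs = a[act] * Vc

    bnd_T = np.zeros(nun)     # transmissibility to the p=0 boundary per unknown
    for ax in range(3):
        # interior faces along ax
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[ax] = slice(0, grid.shape[ax] - 1)
        sl_hi[ax] = slice(1, grid.shape[ax])
        m1 = act[tuple(sl_lo)] & act[tuple(sl_hi)]
        k1 = kmu[tuple(sl_lo)][m1]
        k2 = kmu[tuple(sl_hi)][m1]
        kh = np.where(k1 + k2 > 0, 2.0 * k1 * k2 / np.where(k1 + k2 > 0, k1 + k2, 1.0), 0.0)
        T = kh * areas[ax] / h[ax]
        i1 = idx[tuple(sl_lo)][m1]
        i2 = idx[tuple(sl_hi)][m1]
        rows += [i1, i2, i1, i2]
        cols += [i1, i2, i2, i1]
        vals += [T, T, -T, -T]
        # domain-boundary faces: Dirichlet p=0 at the face, half-cell distance
        for side in (0, -1):
            sl = [slice(None)] * 3
            sl[ax] = side
            mb = act[tuple(sl)]
            Tb = kmu[tuple(sl)][mb] * areas[ax] / (0.5 * h[ax])
            ib = idx[tuple(sl)][mb]
            np.add.at(bnd_T, ib, Tb)

    diag = diag + bnd_T
    rows.append(np.arange(nun))
    cols.append(np.arange(nun))
    vals.append(diag)
    A = sp.csr_matrix((np.concatenate(vals),
                       (np.concatenate(rows), np.concatenate(cols))),
                      shape=(nun, nun))

    if Q_in > 0:
        if catheter is None:
            raise ValueError("an infusion rate requires a catheter")
        tip = catheter.validate(grid)
        if idx[tip] < 0:
            raise ValueError("catheter tip is not an active tissue cell")
        rhs[idx[tip]] += Q_in

    scale = A.diagonal()
    if np.any(scale <= 0):
        raise RuntimeError("singular flow system (isolated cell with no connections)")
    D = sp.diags(1.0 / np.sqrt(scale))
    As = D @ A @ D
    bs = D @ rhs
    x, info = spla.cg(As, bs, rtol=rtol, atol=0.0, maxiter=20000)
    if info != 0:
        x = spla.spsolve(A.tocsc(), rhs)
    else:
        x = D @ x
    res = np.linalg.norm(A @ x - rhs) / max(np.linalg.norm(rhs), 1e-300)
    if res > 1e-6:
        raise RuntimeError(f"flow solver did not converge: relative residual {res:.2e}")

    p = np.zeros(grid.shape)
    p[act] = x

    # face velocities (Darcy superficial): shape (n+1) along each axis
    v_face = []
    bnd_out = 0.0
    for ax in range(3):
        shp = list(grid.shape)
        shp[ax] += 1
        v = np.zeros(shp)
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[ax] = slice(0, grid.shape[ax] - 1)
        sl_hi[ax] = slice(1, grid.shape[ax])
        m1 = act[tuple(sl_lo)] & act[tuple(sl_hi)]
        k1 = kmu[tuple(sl_lo)]
        k2 = kmu[tuple(sl_hi)]
        with np.errstate(divide="ignore", invalid="ignore"):
            kh = np.where(k1 + k2 > 0, 2.0 * k1 * k2 / np.where(k1 + k2 > 0, k1 + k2, 1.0), 0.0)
        dp = (p[tuple(sl_hi)] - p[tuple(sl_lo)]) / h[ax]
        sl_face = [slice(None)] * 3
        sl_face[ax] = slice(1, grid.shape[ax])
        v[tuple(sl_face)] = np.where(m1, -kh * dp, 0.0)
        # boundary faces: Dirichlet p=0 at the face; sgn is the outward axis sign
        for side, face_i, sgn in ((0, 0, -1.0), (-1, grid.shape[ax], 1.0)):
            sl = [slice(None)] * 3
            sl[ax] = side
            mb = act[tuple(sl)]
            v_out = kmu[tuple(sl)] * p[tuple(sl)] / (0.5 * h[ax])  # outward-normal
            sl_f = [slice(None)] * 3
            sl_f[ax] = face_i
            v[tuple(sl_f)] = np.where(mb, sgn * v_out, 0.0)        # axis component
            bnd_out += float(np.sum(np.where(mb, v_out, 0.0)) * areas[ax])
        v_face.append(v)

    F_BL = np.where(act, starling_source(p, vasc, phi_f), 0.0)
    fbl_tot = float(F_BL[act].sum() * Vc)
    denom = max(abs(fbl_tot) + Q_in, 1e-300)
    balance = {"boundary_outflow_m3s": bnd_out,
               "transvascular_m3s": fbl_tot,
               "infused_m3s": float(Q_in),
               "relative_imbalance": abs(bnd_out - fbl_tot - Q_in) / denom,
               "solver_residual": res}
    return FlowState(p=p, v_face=tuple(v_face), F_BL=F_BL, balance=balance)
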