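"""DCE-MRI quantification: SPGR signal model, T10 estimation, LTKM fitting,
and derivation of the simulation's tissue-property maps.

The chain mirrors a standard T1-perfusion workflow: the spoiled-gradient-echo
(SPGR/FFE) steady-state equation converts contrast-agent concentration to a
signal enhancement ratio I(t)/I(0); pre-contrast T1 (T10) comes from three
fast-spin-echo acquisitions; per-voxel tracer-kinetic fitting uses the Leaky
Tracer Kinetic Model (LTKM), an extended-Tofts-type model with an extra
cumulative leakage term lambda_tr suited to short (~2 min) acquisitions.

Units: concentrations in mM for contrast agent, times in seconds, rates in
s^-1, relaxivities in mM^-1 s^-1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, least_squares, minimize_scalar


@dataclass
class AcquisitionParams:
    """SPGR acquisition parameters (defaults: 3T T1-perfusion brain protocol)."""

    TR_s: float = 6.27e-3
    TE_s: float = 3.0e-3
    flip_rad: float = np.deg2rad(10.0)
    R1_per_mM_s: float = 3.5
    R2_per_mM_s: float = 4.9
    dt_s: float = 3.8

    def __post_init__(self):
        if min(self.TR_s, self.TE_s, self.R1_per_mM_s, self.R2_per_mM_s,
               self.dt_s) <= 0:
            raise ValueError("acquisition parameters must be positive")
        if not (0 < self.flip_rad < np.pi / 2):
            raise ValueError("flip angle must lie in (0, pi/2)")


@dataclass
class AIFCurve:
    """Arterial input function: blood contrast concentration C_Gd,BL(t)."""

    times_s: np.ndarray
    cb_mM: np.ndarray

    def __post_init__(self):
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.cb_mM = np.asarray(self.cb_mM, dtype=float)
        if self.times_s.shape != self.cb_mM.shape:
            raise ValueError("times and concentrations must have equal length")
        if np.any(np.diff(self.times_s) <= 0):
            raise ValueError("AIF times must be strictly increasing")
        if np.any(self.cb_mM < 0):
            raise ValueError("AIF concentrations must be nonnegative")


@dataclass
class PerfusionMaps:
    """Voxelwise LTKM parameter fields (plasma fraction, Ktrans, ECS fraction, lambda_tr)."""

    epsBL: np.ndarray
    ktrans_s: np.ndarray
    epsECS: np.ndarray
    lambda_tr_s: np.ndarray

    def __post_init__(self):
        shapes = {f.shape for f in (self.epsBL, self.ktrans_s,
                                    self.epsECS, self.lambda_tr_s)}
        if len(shapes) != 1:
            raise ValueError("perfusion maps must share one grid shape")

    @property
    def shape(self):
        return self.epsBL.shape


@dataclass
class VoxelFit:
    params: np.ndarray   # (epsBL, ktrans_s, epsECS, lambda_tr_s)
    rss: float
    converged: bool


# ---------------------------------------------------------------- SPGR model

def _spgr_E(c_mM, t10_s, acq):
    return np.exp(-acq.TR_s * (1.0 / t10_s + acq.R1_per_mM_s * c_mM))


def spgr_signal_ratio(c_mM, t10_s, acq: AcquisitionParams):
    """Signal enhancement ratio I(t)/I(0) of the SPGR sequence.

    ratio = k0 * exp(-TE*R2*C) * (1-E)/(1-cos(theta)*E),
    E = exp(-TR*(1/T10 + R1*C)), and k0 chosen so the ratio is exactly 1 at C=0.
    """
    c_mM = np.asarray(c_mM, dtype=float)
    t10_s = np.asarray(t10_s, dtype=float)
    if np.any(t10_s <= 0):
        raise ValueError("T10 must be positive")
    if np.any(c_mM < 0):
        raise ValueError("concentration must be nonnegative")
    cos_t = np.cos(acq.flip_rad)
    E0 = np.exp(-acq.TR_s / t10_s)
    k0 = (1.0 - cos_t * E0) / (1.0 - E0)
    E = _spgr_E(c_mM, t10_s, acq)
    out = k0 * np.exp(-acq.TE_s * acq.R2_per_mM_s * c_mM) * (1.0 - E) / (1.0 - cos_t * E)
    return out if out.shape else float(out)


def spgr_peak_concentration(t10_s, acq: AcquisitionParams, c_max_mM=50.0):
    """First stationary point C* of the ratio-vs-concentration curve.

    The enhancement ratio rises with C (T1 shortening) then falls (T2*
    decay); inversion is restricted to the monotone branch [0, C*].
    """
    res = minimize_scalar(lambda c: -spgr_signal_ratio(c, t10_s, acq),
                          bounds=(0.0, c_max_mM), method="bounded",
                          options={"xatol": 1e-10})
    return float(res.x)


def concentration_from_signal(ratio, t10_s, acq: AcquisitionParams,
                              tol_mM=1e-9):
    """Invert the SPGR equation: smallest nonnegative C with ratio(C)=ratio.

    Ratios below 1 (noise pushing the signal under baseline) clamp to 0 mM.
    Ratios above the achievable maximum on the monotone branch are an error.
    """
    ratio = float(ratio)
    if ratio <= 0:
        raise ValueError("signal ratio must be positive")
    if ratio <= 1.0:
        return 0.0
    c_star = spgr_peak_concentration(t10_s, acq)
    r_max = spgr_signal_ratio(c_star, t10_s, acq)
    if ratio > r_max:
        raise ValueError(
            f"ratio {ratio:.4g} exceeds the SPGR maximum {r_max:.4g} "
            f"attainable at C*={c_star:.4g} mM (T10={t10_s} s)")
    return brentq(lambda c: spgr_signal_ratio(c, t10_s, acq) - ratio,
                  0.0, c_star, xtol=tol_mM)


# ------------------------------------------------------------ T10 estimation

@dataclass
class FSEParams:
    """TR/TE (s) of the three fast-spin-echo acquisitions used for T10."""

    TR_t1w_s: float = 0.360
    TE_t1w_s: float = 0.010
    TR_t2w_s: float = 3.500
    TE_t2w_s: float = 0.090
    TR_pd_s: float = 3.500
    TE_pd_s: float = 0.0072


def fse_signal(t1_s, t2_s, TR_s, TE_s, m0=1.0):
    """Forward FSE signal model S = M0 (1 - exp(-TR/T1)) exp(-TE/T2)."""
    return m0 * (1.0 - np.exp(-TR_s / t1_s)) * np.exp(-TE_s / t2_s)


def estimate_t10(s_t1w, s_t2w, s_pd, fse: FSEParams | None = None,
                 t1_bracket_s=(0.02, 20.0)):
    """Per-voxel pre-contrast T1 from T1w / T2w / PD fast-spin-echo signals.

    The T2w and PD images share TR, so their ratio isolates T2:
    T2 = (TE_t2w - TE_pd) / ln(S_pd / S_t2w).  With T2 known, T1 solves the
    T1w/PD ratio equation.  Degenerate voxels (nonpositive signals or
    S_pd <= S_t2w) are flagged NaN and excluded.

    Returns (t10_s, valid_mask), both shaped like the inputs.
    """
    fse = fse or FSEParams()
    s1 = np.asarray(s_t1w, dtype=float)
    s2 = np.asarray(s_t2w, dtype=float)
    sp = np.asarray(s_pd, dtype=float)
    if not (s1.shape == s2.shape == sp.shape):
        raise ValueError("the three FSE images must share one shape")
    if abs(fse.TR_t2w_s - fse.TR_pd_s) > 1e-12:
        raise ValueError("T2w and PD acquisitions must share TR for the ratio method")
    valid = (s1 > 0) & (s2 > 0) & (sp > 0) & (sp > s2)
    t10 = np.full(s1.shape, np.nan)
    t2 = np.full(s1.shape, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        t2[valid] = (fse.TE_t2w_s - fse.TE_pd_s) / np.log(sp[valid] / s2[valid])

    lo, hi = t1_bracket_s
    it = np.ndindex(s1.shape) if s1.shape else [()]
    for idx in it:
        if not (valid[idx] if s1.shape else valid):
            continue
        t2v = t2[idx] if s1.shape else float(t2)
        # ratio S_t1w/S_pd with the T2 decay factored out
        target = ((s1[idx] / sp[idx]) if s1.shape else s1 / sp) \
            * np.exp((fse.TE_t1w_s - fse.TE_pd_s) / t2v)

        def f(t1):
            return (1.0 - np.exp(-fse.TR_t1w_s / t1)) \
                / (1.0 - np.exp(-fse.TR_pd_s / t1)) - target

        if f(lo) * f(hi) > 0:
            valid[idx] = False
            continue
        t10[idx] = brentq(f, lo, hi, xtol=1e-9)
    if not s1.shape:
        return float(t10), bool(valid)
    return t10, valid


# ------------------------------------------------------------------- LTKM

def ltkm_forward(epsBL, ktrans_s, epsECS, lambda_tr_s, aif: AIFCurve,
                 times_s=None):
    """Tissue contrast concentration C_Gd,ECS(t) of the LTKM.

    C(t) = epsBL*Cb(t)
         + Ktrans * int_0^t Cb(tau) exp(Ktrans/epsECS * (tau - t)) dtau
         + lambda_tr * int_0^t Cb(tau) dtau

    Integrals use trapezoid quadrature on the AIF sampling.
    """
    if times_s is None:
        times_s = aif.times_s
    times_s = np.asarray(times_s, dtype=float)
    if times_s.min() < aif.times_s[0] - 1e-12 or times_s.max() > aif.times_s[-1] + 1e-12:
        raise ValueError("requested times fall outside the AIF support")
    if not (0 <= epsBL <= 1) or not (0 <= epsECS <= 1):
        raise ValueError("volume fractions must lie in [0, 1]")
    if ktrans_s < 0 or lambda_tr_s < 0:
        raise ValueError("rates must be nonnegative")
    if ktrans_s > 0 and epsECS <= 0:
        raise ValueError("epsECS must be positive when Ktrans > 0")

    t = aif.times_s
    cb = aif.cb_mM
    out = np.empty(times_s.shape)
    kep = ktrans_s / epsECS if ktrans_s > 0 else 0.0
    for i, ti in enumerate(times_s):
        m = t <= ti + 1e-12
        tm, cm = t[m], cb[m]
        if tm.size and abs(tm[-1] - ti) > 1e-12:
            # end the quadrature exactly at ti
            ci = np.interp(ti, t, cb)
            tm = np.append(tm, ti)
            cm = np.append(cm, ci)
        cb_i = np.interp(ti, t, cb)
        if tm.size < 2:
            out[i] = epsBL * cb_i
            continue
        conv = np.trapezoid(cm * np.exp(kep * (tm - ti)), tm) if ktrans_s > 0 else 0.0
        leak = np.trapezoid(cm, tm)
        out[i] = epsBL * cb_i + ktrans_s * conv + lambda_tr_s * leak
    return out


_LTKM_BOUNDS = (np.array([0.0, 0.0, 1e-6, 0.0]),
                np.array([1.0, 1.0, 1.0, 1.0]))

_LTKM_STARTS = np.array([
    [0.02, 2e-3, 0.3, 1e-4],
    [0.10, 1e-2, 0.6, 1e-3],
    [0.005, 5e-4, 0.1, 1e-5],
])


def fit_ltkm(curve_mM, aif: AIFCurve, times_s=None, gtkm=False) -> VoxelFit:
    """Bounded nonlinear least-squares LTKM fit of one voxel curve.

    Three fixed multi-starts; the lowest-RSS solution wins (ties broken by
    lower lambda_tr).  ``gtkm=True`` fixes lambda_tr=0, giving the General
    Tracer Kinetic Model.
    """
    if times_s is None:
        times_s = aif.times_s
    curve = np.asarray(curve_mM, dtype=float)
    times_s = np.asarray(times_s, dtype=float)
    if curve.shape != times_s.shape or curve.size < 8:
        raise ValueError("curve and times must share a length of at least 8")
    if not (np.all(np.isfinite(curve)) and np.all(np.isfinite(times_s))):
        raise ValueError("non-finite input")

    if not np.any(curve != 0):
        return VoxelFit(params=np.zeros(4), rss=0.0, converged=True)

    def resid(p):
        eB, kt, eE, lt = p
        return ltkm_forward(eB, kt, eE, 0.0 if gtkm else lt, aif, times_s) - curve

    best = None
    for start in _LTKM_STARTS:
        p0 = start.copy()
        if gtkm:
            p0[3] = 0.0
        try:
            sol = least_squares(resid, p0, bounds=_LTKM_BOUNDS,
                                xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=400)
        except Exception:
            continue
        rss = float(np.sum(sol.fun ** 2))
        cand = (rss, float(sol.x[3]), sol)
        if best is None or cand[:2] < best[:2]:
            best = cand
    if best is None:
        raise RuntimeError("all LTKM fit starts failed")
    rss, _, sol = best
    params = sol.x.copy()
    if gtkm:
        params[3] = 0.0
    return VoxelFit(params=params, rss=rss, converged=bool(sol.status > 0))


def fit_ltkm_volume(series_mM, aif: AIFCurve, mask=None, times_s=None):
    """Fit every masked voxel of a (nx,ny,nz,nt) concentration series.

    Returns (PerfusionMaps, rss_field, converged_field); unmasked voxels are
    zero-parameter.
    """
    series = np.asarray(series_mM, dtype=float)
    shp = series.shape[:3]
    if mask is None:
        mask = np.ones(shp, dtype=bool)
    fields = [np.zeros(shp) for _ in range(4)]
    rss = np.zeros(shp)
    conv = np.ones(shp, dtype=bool)
    for idx in np.argwhere(mask):
        fit = fit_ltkm(series[tuple(idx)], aif, times_s=times_s)
        for k in range(4):
            fields[k][tuple(idx)] = fit.params[k]
        rss[tuple(idx)] = fit.rss
        conv[tuple(idx)] = fit.converged
    maps = PerfusionMaps(epsBL=fields[0], ktrans_s=fields[1],
                         epsECS=fields[2], lambda_tr_s=fields[3])
    return maps, rss, conv


# ------------------------------------------------- property-map derivation

CM_ICS_RATIO_TUMOR = 0.154
CM_ICS_RATIO_NORMAL = 0.188
SV_BASELINE_TUMOR = 2.0e4     # (S_BL/V_T)_b, m^-1
SV_BASELINE_NORMAL = 7.0e3


@dataclass
class TissueProperties:
    """Per-voxel initial tissue state consumed by the flow/transport solvers.

    Volume fractions close to 1 at every tissue voxel:
    epsBL + epsECS + epsCM + epsICS = 1.  ``sv0`` is the initial microvascular
    surface area per unit tissue volume S_BL,0/V_T (m^-1), scaled voxelwise by
    Ktrans relative to its tumor average.
    """

    epsBL0: np.ndarray
    epsECS0: np.ndarray
    epsCM: np.ndarray
    epsICS: np.ndarray
    sv0: np.ndarray
    ktrans_s: np.ndarray = None
    clipped: np.ndarray = None


def derive_property_maps(maps: PerfusionMaps, tumor_mask, tissue_mask=None,
                         cm_ics_ratio_tumor=CM_ICS_RATIO_TUMOR,
                         cm_ics_ratio_normal=CM_ICS_RATIO_NORMAL,
                         sv_baseline_tumor=SV_BASELINE_TUMOR,
                         sv_baseline_normal=SV_BASELINE_NORMAL) -> TissueProperties:
    """Close the volume-fraction budget and scale microvascular surface density.

    Per voxel: epsICS = (1 - epsBL - epsECS)/(1 + r), epsCM = r*epsICS with the
    cell-membrane/intracellular ratio r = 0.154 (tumor) or 0.188 (normal);
    S_BL,0/V_T = (Ktrans / Ktrans_avg_tumor) * (S/V)_b per region, the tumor
    average taken over the tumor mask only.  Exterior voxels stay all-zero.
    Voxels with epsBL+epsECS > 1 are clipped (epsECS reduced) and flagged.
    """
    tumor_mask = np.asarray(tumor_mask, dtype=bool)
    if tissue_mask is None:
        tissue_mask = np.ones(tumor_mask.shape, dtype=bool)
    tissue_mask = np.asarray(tissue_mask, dtype=bool)

    eB = np.where(tissue_mask, maps.epsBL, 0.0).copy()
    eE = np.where(tissue_mask, maps.epsECS, 0.0).copy()
    kt = np.where(tissue_mask, maps.ktrans_s, 0.0)

    clipped = tissue_mask & (eB + eE > 1.0)
    if np.any(clipped):
        import warnings
        warnings.warn(f"{int(clipped.sum())} voxels had epsBL+epsECS > 1; epsECS clipped")
        eE[clipped] = np.maximum(1.0 - eB[clipped], 0.0)

    ratio = np.where(tumor_mask, cm_ics_ratio_tumor, cm_ics_ratio_normal)
    rest = np.clip(1.0 - eB - eE, 0.0, None)
    eI = np.where(tissue_mask, rest / (1.0 + ratio), 0.0)
    eC = np.where(tissue_mask, ratio * eI, 0.0)

    if not np.any(tumor_mask):
        raise ValueError("tumor mask is empty; cannot form Ktrans tumor average")
    kavg = float(np.mean(kt[tumor_mask]))
    if kavg <= 0:
        raise ValueError("tumor-average Ktrans is nonpositive")
    svb = np.where(tumor_mask, sv_baseline_tumor, sv_baseline_normal)
    sv0 = np.where(tissue_mask, kt / kavg * svb, 0.0)

    return TissueProperties(epsBL0=eB, epsECS0=eE, epsCM=eC, epsICS=eI,
                            sv0=sv0, ktrans_s=kt, clipped=clipped)
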