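"""Synthetic heterogeneous-tissue phantom, arterial input function, and 4D DCE series.

The phantom replaces patient imaging: a box of normal brain tissue encloses an
ellipsoidal tumor whose plasma volume fraction, intracellular fraction,
Ktrans and leakage constant are smoothly correlated Gaussian random fields.
The forward DCE chain (LTKM tissue curves -> SPGR signal ratios -> noisy
intensities) produces series that the `dce` module can invert, so the whole
quantification pipeline is testable without any acquisition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from . import dce
from .grid import (EXTERIOR, NORMAL, TUMOR, StructuredGrid, build_grid,
                   ellipsoid_mask)

# Homogeneous normal-tissue defaults (plasma fraction, ECS fraction, Ktrans as a
# fraction of the tumor mean, leakage constant).  Normal brain has an intact
# BBB, hence modest plasma fraction and transvascular rates.
NORMAL_EPSBL = 0.01
NORMAL_EPSECS = 0.20
NORMAL_KTRANS_FRAC = 0.2
NORMAL_LAMBDA_TR = 5e-5
NORMAL_T10_S = 1.0
TUMOR_T10_S = 1.4
EPSECS_FLOOR = 0.02


@dataclass
class PhantomSpec:
    """Parameters of the synthetic tissue phantom.

    Ranges are the spans the generated tumor fields are affinely rescaled
    into; defaults reproduce the spans observed in the quantified patient
    tumor (plasma fraction 2.22e-14..9.66e-2, intracellular fraction
    0.5808..0.999, the latter capped by volume-fraction feasibility).
    """

    grid_dims_mm: tuple = (45.0, 45.0, 45.0)
    voxel_mm: tuple = (1.5, 1.5, 1.5)
    tumor_center_mm: tuple = (22.5, 22.5, 22.5)
    tumor_radii_mm: tuple = (12.0, 10.5, 10.5)
    epsBL_range: tuple = (2.22e-14, 9.66e-2)
    epsICS_range: tuple = (5.808e-1, 9.99e-1)
    ktrans_mean_s: float = 5.0e-3
    lambda_tr_range_s: tuple = (1.0e-5, 3.0e-4)
    heterogeneity_corr_len_mm: float = 6.0
    vasc_skew: float = 3.0
    cell_vasc_corr: float = -0.5
    noise_sd_frac: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for lo, hi in (self.epsBL_range, self.epsICS_range):
            if not (0.0 <= lo <= hi <= 1.0):
                raise ValueError("fraction ranges must satisfy 0 <= low <= high <= 1")
        if np.any(np.asarray(self.voxel_mm) <= 0) or np.any(np.asarray(self.tumor_radii_mm) <= 0):
            raise ValueError("voxel sizes and tumor radii must be positive")
        if self.ktrans_mean_s <= 0 or self.heterogeneity_corr_len_mm <= 0:
            raise ValueError("ktrans mean and correlation length must be positive")
        lo = np.asarray(self.tumor_center_mm) - np.asarray(self.tumor_radii_mm)
        hi = np.asarray(self.tumor_center_mm) + np.asarray(self.tumor_radii_mm)
        if np.any(lo < 0) or np.any(hi > np.asarray(self.grid_dims_mm)):
            raise ValueError("tumor ellipsoid must lie fully inside the domain")


@dataclass
class AIFParams:
    """Delayed double-exponential bolus: cb(t) = A1 e^{-m1 tau} - A2 e^{-m2 tau},
    tau = t - t0, zero before arrival.  Nonnegativity needs A1 >= A2 >= 0 and
    m2 >= m1."""

    A1_mM: float = 6.0
    A2_mM: float = 6.0
    m1_per_s: float = 0.008
    m2_per_s: float = 0.05
    t0_s: float = 10.0

    def mode_s(self) -> float:
        """Closed-form time of the curve maximum (for A2 m2 > A1 m1 > 0)."""
        if self.A1_mM == 0 and self.A2_mM == 0:
            return self.t0_s
        num = self.A2_mM * self.m2_per_s
        den = self.A1_mM * self.m1_per_s
        if not num > den > 0:
            raise ValueError("mode undefined unless A2*m2 > A1*m1 > 0")
        return self.t0_s + np.log(num / den) / (self.m2_per_s - self.m1_per_s)


def synth_aif(times_s, params: AIFParams | None = None) -> dce.AIFCurve:
    """Parametric arterial input function sampled at ``times_s``."""
    params = params or AIFParams()
    if params.A1_mM < 0 or params.A2_mM < 0:
        raise ValueError("AIF amplitudes must be nonnegative")
    if params.A2_mM > params.A1_mM or params.m2_per_s < params.m1_per_s:
        raise ValueError("nonnegativity requires A1 >= A2 and m2 >= m1")
    t = np.asarray(times_s, dtype=float)
    tau = t - params.t0_s
    cb = np.where(tau > 0,
                  params.A1_mM * np.exp(-params.m1_per_s * np.clip(tau, 0, None))
                  - params.A2_mM * np.exp(-params.m2_per_s * np.clip(tau, 0, None)),
                  0.0)
    return dce.AIFCurve(times_s=t, cb_mM=np.clip(cb, 0.0, None))


@dataclass
class Phantom:
    """Generated phantom bundle: grid + perfusion maps + derived tissue state."""

    grid: StructuredGrid
    maps: dce.PerfusionMaps
    tissue: dce.TissueProperties
    t10_s: np.ndarray
    spec: PhantomSpec = field(repr=False, default=None)


def _smooth_field(rng, shape, sigma_cells):
    """Standardized Gaussian random field with the requested correlation length."""
    f = gaussian_filter(rng.standard_normal(shape), sigma=sigma_cells, mode="nearest")
    sd = f.std()
    return (f - f.mean()) / (sd if sd > 0 else 1.0)


def _unit(f, mask):
    """Affine map onto [0, 1] over ``mask`` (min -> 0, max -> 1)."""
    ref = f[mask]
    lo, hi = ref.min(), ref.max()
    if hi - lo < 1e-300:
        return np.full(f.shape, 0.5)
    return np.clip((f - lo) / (hi - lo), 0.0, 1.0)


def _rescale(u, lo, hi):
    return lo + u * (hi - lo)


def generate_tissue_maps(spec: PhantomSpec) -> Phantom:
    """Generate the heterogeneous tumor-in-brain property fields.

    Tumor voxels get smoothly correlated random fields: plasma fraction in
    ``epsBL_range``, intracellular fraction in ``epsICS_range`` (capped so the
    ECS fraction keeps a small floor), Ktrans monotone in the plasma-fraction
    latent field (vascular hot spots are also leaky), and a leakage constant.
    Normal voxels carry homogeneous defaults; exterior voxels are all-zero.
    The ECS fraction follows from the closure eBL+eECS+eCM+eICS=1 with
    eCM = r*eICS (r = 0.154 tumor / 0.188 normal).
    """
    g = build_grid(spec.grid_dims_mm, spec.voxel_mm)
    tumor = ellipsoid_mask(g, spec.tumor_center_mm, spec.tumor_radii_mm)
    g.region[...] = NORMAL
    g.region[tumor] = TUMOR

    rng = np.random.default_rng(spec.seed)
    sigma = np.asarray(spec.heterogeneity_corr_len_mm) / np.asarray(spec.voxel_mm)

    z_vasc = _smooth_field(rng, g.shape, sigma)
    z_ind = _smooth_field(rng, g.shape, sigma)
    z_leak = _smooth_field(rng, g.shape, sigma)
    # cell density anti-correlates with vascularity (densely cellular regions
    # are poorly perfused), controlled by cell_vasc_corr
    rho = float(np.clip(spec.cell_vasc_corr, -1.0, 1.0))
    z_cell = rho * z_vasc + np.sqrt(1.0 - rho ** 2) * z_ind
    u_vasc = _unit(z_vasc, tumor)       # shared vascular latent
    u_cell = _unit(z_cell, tumor)
    u_leak = _unit(z_leak, tumor)

    # Vascularity histograms of DCE-quantified gliomas are strongly
    # right-skewed (large poorly-perfused regions, localized hot spots); the
    # unit latent is pushed through a power law before rescaling.
    u_sk = u_vasc ** spec.vasc_skew
    epsBL = np.full(g.shape, NORMAL_EPSBL)
    epsBL[tumor] = _rescale(u_sk, *spec.epsBL_range)[tumor]

    # Ktrans monotone in the same vascular latent (hot spots are also leaky),
    # with a small floor so the tumor average stays well defined.
    ktrans = np.full(g.shape, NORMAL_KTRANS_FRAC * spec.ktrans_mean_s)
    ktrans[tumor] = spec.ktrans_mean_s * (0.02 + 2.4 * u_sk[tumor])

    lam = np.full(g.shape, NORMAL_LAMBDA_TR)
    lam[tumor] = _rescale(u_leak, *spec.lambda_tr_range_s)[tumor]

    # Intracellular fraction, capped so epsECS >= EPSECS_FLOOR under closure.
    r_t = dce.CM_ICS_RATIO_TUMOR
    epsICS_t = _rescale(u_cell, *spec.epsICS_range)
    cap = (1.0 - epsBL - EPSECS_FLOOR) / (1.0 + r_t)
    epsICS_t = np.minimum(epsICS_t, cap)
    epsECS = np.full(g.shape, NORMAL_EPSECS)
    epsECS[tumor] = (1.0 - epsBL - (1.0 + r_t) * epsICS_t)[tumor]

    maps = dce.PerfusionMaps(epsBL=epsBL, ktrans_s=ktrans,
                             epsECS=epsECS, lambda_tr_s=lam)
    tissue = dce.derive_property_maps(maps, tumor_mask=tumor,
                                      tissue_mask=g.tissue_mask)
    t10 = np.where(tumor, TUMOR_T10_S, NORMAL_T10_S)
    t10[g.region == EXTERIOR] = np.nan
    return Phantom(grid=g, maps=maps, tissue=tissue, t10_s=t10, spec=spec)


def ltkm_forward_volume(maps: dce.PerfusionMaps, aif: dce.AIFCurve,
                        mask=None) -> np.ndarray:
    """Vectorized LTKM forward model over a volume, at the AIF sampling.

    Uses the same trapezoid quadrature as :func:`cedsim.dce.ltkm_forward`;
    returns a (nx, ny, nz, nt) tissue-concentration array (mM).
    """
    shp = maps.shape
    if mask is None:
        mask = np.ones(shp, dtype=bool)
    t = aif.times_s
    cb = aif.cb_mM
    nt = t.size
    eB = maps.epsBL[mask]
    kt = maps.ktrans_s[mask]
    eE = np.clip(maps.epsECS[mask], 1e-12, None)
    lt = maps.lambda_tr_s[mask]
    kep = np.where(kt > 0, kt / eE, 0.0)[:, None]        # (nv, 1)

    # cumulative trapezoid of the AIF
    leak = np.concatenate([[0.0], np.cumsum(0.5 * (cb[1:] + cb[:-1]) * np.diff(t))])

    out = np.zeros((eB.size, nt))
    for i in range(nt):
        tm = t[: i + 1]
        cm = cb[: i + 1]
        if i >= 1:
            integrand = cm[None, :] * np.exp(kep * (tm[None, :] - t[i]))
            conv = np.trapezoid(integrand, tm, axis=1)
        else:
            conv = np.zeros(eB.size)
        out[:, i] = eB * cb[i] + kt * conv + lt * leak[i]

    vol = np.zeros(shp + (nt,))
    vol[mask] = out
    return vol


def generate_dce_series(maps: dce.PerfusionMaps, aif: dce.AIFCurve,
                        acq: dce.AcquisitionParams, t10_map, spec: PhantomSpec,
                        baseline_intensity=1000.0, tissue_mask=None):
    """Forward 4D DCE signal series: LTKM tissue curves -> SPGR intensities.

    Per voxel the contrast concentration C_Gd,ECS(t) is converted to a signal
    ratio by the SPGR model and multiplied by a baseline intensity; Gaussian
    noise of sd ``spec.noise_sd_frac * baseline`` is added when nonzero.
    Non-tissue voxels emit a flat baseline signal.
    """
    t10_map = np.asarray(t10_map, dtype=float)
    if t10_map.shape != maps.shape:
        raise ValueError("T10 map shape does not match the perfusion maps")
    if tissue_mask is None:
        tissue_mask = np.isfinite(t10_map) & (t10_map > 0)
    conc = ltkm_forward_volume(maps, aif, mask=tissue_mask)

    nt = aif.times_s.size
    sig = np.full(maps.shape + (nt,), baseline_intensity, dtype=float)
    cvox = conc[tissue_mask]                     # (nv, nt)
    t10v = t10_map[tissue_mask][:, None]
    ratio = dce.spgr_signal_ratio(cvox, np.broadcast_to(t10v, cvox.shape), acq)
    sig[tissue_mask] = baseline_intensity * ratio

    if spec.noise_sd_frac > 0:
        rng = np.random.default_rng(spec.seed + 1)
        sig = sig + rng.normal(0.0, spec.noise_sd_frac * baseline_intensity,
                               size=sig.shape)
    return sig


def invert_dce_series(signal, t10_map, acq: dce.AcquisitionParams,
                      tissue_mask=None, baseline_frames=1):
    """Signal series -> contrast-concentration series (mM), voxel by voxel.

    The pre-bolus frames estimate I(0); each sample is then inverted through
    the SPGR monotone branch.
    """
    signal = np.asarray(signal, dtype=float)
    t10_map = np.asarray(t10_map, dtype=float)
    if tissue_mask is None:
        tissue_mask = np.isfinite(t10_map) & (t10_map > 0)
    conc = np.zeros_like(signal)
    for idx in np.argwhere(tissue_mask):
        idx = tuple(idx)
        s = signal[idx]
        s0 = float(np.mean(s[:baseline_frames]))
        for i, si in enumerate(s):
            conc[idx + (i,)] = dce.concentration_from_signal(
                max(si / s0, 1e-12), t10_map[idx], acq)
    return conc
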