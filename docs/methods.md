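# Methods

`cedsim` simulates convection-enhanced delivery (CED) of a combination
therapy — an antiangiogenic antibody (bevacizumab-like, "BEV") co-infused
with a cytotoxic drug (temozolomide-like, "TMZ", either free or
liposome-encapsulated) — into a heterogeneous brain tumor, with the tumor's
per-voxel biological properties quantified from DCE-MRI-type signals.  This
note records the model, its assumptions, the numerical choices, and what the
synthetic phantom does and does not emulate.

## Interstitial fluid flow

Tumor and normal tissue are rigid porous media.  The capillary bed acts as a
distributed fluid source per Starling's law,

    F_BL = L_BL (φ S0/V) [p_BL − p − σ (π_BL − π_ISF)]   [1/s],

and continuity plus Darcy's law give one elliptic problem for the
interstitial fluid pressure p:

    −∇·( (κ/μ) ∇p ) = F_BL(p) + q_in,

with p = 0 (gauge) on the outer boundary, no-flux at exterior (air) and
catheter-shaft cells, and the infusion as a volumetric source q_in =
Q_in/V_cell in the catheter-tip cell.  The full momentum balance also
contains inertia and Brinkman shear; at interstitial velocities (≲ µm/s) and
κ ~ 1e-14 m², the Darcy drag term exceeds them by more than six orders of
magnitude, so the quasi-steady Darcy form is solved and re-solved whenever
the vascular scaling φ has moved by more than a threshold (default 0.01).
The density ρ is kept in `FluidProperties` but unused by the reduced solver.

Discretization: cell-centered finite volumes on a uniform (possibly
anisotropic) grid, harmonic-mean face permeabilities, half-cell Dirichlet
closure at the outer boundary.  The Starling term is linear in p and sits on
the matrix diagonal, so the system is SPD; it is solved by
Jacobi-preconditioned conjugate gradients to 1e-10 relative residual (direct
sparse fallback).  The discrete budget (boundary outflow = transvascular
gain + infusion) closes to ~1e-10 relative.

Verification uses two analytic limits: a point source in a homogeneous
medium against the free-space Green's function p = Qµ/(4πκr), and the 0-D
Starling equilibrium p = p_BL − σ(π_BL − π_ISF) = 2699.4 Pa in a very large
all-tumor medium.  A grounded finite box superposes a nearly uniform
background on the 1/r field (≈ Qµ/4πκR_eff); the comparison therefore
measures this monopole offset on a far shell and removes it — the standard
finite-domain correction — after which shell-averaged pressures agree with
the Green's function to well under 5% from two cell widths outward.

The infusion-site pressure itself is grid- and boundary-detail dependent
(with a volumetric tip source it is of order 1e1–1e3 Pa for the baseline
parameters, far below the >1e5 Pa reported for real catheters, which
concentrate the flux on a sub-millimeter surface); the package therefore
checks the *behavior* of the tip pressure — above the no-infusion
equilibrium, linear in Q_in, inverse in κ — rather than a magnitude.

## Drug transport

Three species move on the Darcy velocity field with per-region diffusivities
and linear kinetics (all drug parameters in `transport.DrugLibrary`, volumes
as concentration × volume-fraction per tissue volume):

* **Liposome-encapsulated drug** (capacity ε_ECS): releases free drug at
  k_rel and leaks to blood at k_LP,b = P_TV,LP · φS0/V.
* **Free drug** (capacity ω = ε_ECS(1+K_BC) + ε_ICS H_IE(1+K_BC) + ε_CM H_CE,
  reflecting instantaneous protein binding and membrane/cell partitioning):
  sourced by release, drained at ε_ECS k_FD,b, eliminated at
  (ε_ECS + ε_ICS H_IE) k_FD,e.  The elimination prefactor generalizes the
  (ε_ECS + ε_ICS) form, to which it reduces at the default H_IE = 1.
* **Antiangiogenic drug** (capacity ε_ECS): eliminated at k_AA,e.

Advection is implemented in conservative flux form −∇·(v u) on the conserved
variable u = ε_ECS C.  Because the discrete velocity field satisfies
∇·v = F_BL, this is identical to the non-conservative v·∇u form plus the
F_BL·u dilution sink of the continuum equations, but it telescopes exactly
over faces, so the per-species mass ledger (stored + drained + eliminated +
boundary outflow + release transfers = infused) closes to roundoff.  The
same sink form is kept where F_BL < 0 (drug leaves with reabsorbed fluid).

Time stepping: first-order upwind advection and explicit diffusion with an
automatically sub-cycled step bounded by the positivity/stability limit
(≈ 190 s for free drug at 0.9 mm cells; the macro step is capped at 60 s, so
the implicit diffusion alternative buys nothing at these resolutions), and
pointwise reactions advanced by the *exact* exponential solution of the
linear LP→FD chain over each sub-step (rates held at the step's φ).  The
isolated-cell oracles therefore agree with scalar ODE solutions to machine
precision, and nonnegativity is preserved by construction.  Halving the
macro step changes Day-3 tumor averages by <1%.

Boundary conditions: infused species are held at their inlet concentration
in the tip cell for the infusion duration (the tip cell is treated as
external to the mass ledger; the flux leaving it is the infused mass); zero
diffusive flux with free convective outflow on the outer boundary (a strict
zero-total-flux condition would contradict the pressure outlet there);
no-flux at the rigid catheter shaft and at tissue–exterior faces.

## Antiangiogenic feedback

Vascular regression follows the cubic-logistic kinetics

    dφ/dt = φ(α + βφ + γφ²) − k_a φ C_AA,

with the natural-angiogenesis coefficients summing to zero so φ = 1 is
exactly stationary without drug (the other root of the cubic is
α/γ ≈ 0.4987; between the roots φ regrows toward 1).  The update is a
vectorized classical RK4 with sub-steps capped at 0.05 of the fastest local
rate, which tracks an adaptive ODE oracle to ~1e-6 over multi-day horizons.
φ feeds back three ways: the plasma fraction shrinks as ε_BL = φ²ε_BL,0
(vessel radii contract at constant vessel length and tissue volume), the
freed volume joins the extracellular space through the closure
ε_BL+ε_ECS+ε_CM+ε_ICS = 1, and every S/V-proportional quantity (Starling
source, drainage rates) scales linearly with φ.

## DCE quantification

The signal chain is a standard T1-perfusion workflow: the SPGR/FFE
steady-state equation converts contrast concentration to the enhancement
ratio I(t)/I(0) (protocol defaults TR 6.27 ms, TE 3.0 ms, flip 10°, Dotarem
relaxivities R1 3.5 / R2 4.9 mM⁻¹s⁻¹, 3.8 s sampling over ~2 min); inversion
takes the smallest root on the monotone branch [0, C*] by bracketed root
finding (tolerance 1e-9 mM), appropriate for the low-concentration regime of
a short acquisition.  Ratios below 1 clamp to zero.

Pre-contrast T1 comes from three fast-spin-echo images (T1w 360/10, T2w
3500/90, PD 3500/7.2 ms) under the FSE signal model
S ∝ M0(1−e^{−TR/T1})e^{−TE/T2}: the T2w/PD pair shares TR and isolates T2,
then T1 solves the T1w/PD ratio equation by bracketed root finding.  The
method is validated against its own forward model (exact noiseless
recovery; ~1.4% median error at 1% signal noise) — the upstream literature
procedure it stands in for is not published in reproducible detail.

Voxel fitting uses the leaky tracer kinetic model (LTKM), an
extended-Tofts-type model with a cumulative leakage term,

    C(t) = ε_BL c_b(t) + Ktrans ∫ c_b e^{(Ktrans/ε_ECS)(τ−t)} dτ + λ_tr ∫ c_b dτ,

with trapezoid quadrature at the acquisition sampling, bounded nonlinear
least squares (fractions in [0,1], rates in [0,1] s⁻¹), three fixed starts,
best-RSS winner with ties broken toward smaller λ_tr; fixing λ_tr = 0 gives
the general (Tofts) model.  λ_tr is treated as s⁻¹ for dimensional
consistency.  A caveat established here with a Cramér–Rao analysis: over a
2-minute acquisition λ_tr is nearly collinear with the Ktrans term whenever
Ktrans·T/ε_ECS is small, so at 1% noise its per-voxel estimate is
essentially undetermined (relative sd above 100% at typical tumor values)
even though the noiseless fit is exact.  The other three parameters recover
with <10% median error at 1% noise.

Property derivation closes the volume fractions with the cell-membrane /
intracellular ratio 0.154 (tumor) / 0.188 (normal):
ε_ICS = (1−ε_BL−ε_ECS)/(1+r), ε_CM = r·ε_ICS; and scales the baseline
microvascular surface density voxelwise, S0/V = (Ktrans/K̄trans)(S/V)_b with
the tumor-mask average K̄trans and region baselines 2.0e4 / 7.0e3 m⁻¹ (the
normal-tissue baseline choice mirrors the tumor rule; necrotic voxels are
not excluded from K̄trans).  Voxels fitted with ε_BL+ε_ECS > 1 are clipped
(ε_ECS reduced) and flagged.

## Synthetic phantom

The phantom replaces patient imaging: a box of normal tissue (defaults
45 mm³ at 1.5 mm voxels) encloses an ellipsoidal tumor matched to the
reported patient tumor volume (~5.5 cm³).  Tumor fields are Gaussian random
fields (white noise smoothed to a 6 mm correlation length, affinely mapped
onto configured ranges within the tumor mask):

* **Plasma fraction**: the unit latent is cubed before rescaling onto
  (2.22e-14, 9.66e-2).  The huge quantified span implies a mostly
  near-avascular tumor with localized hot spots — the right-skewed histogram
  typical of glioblastoma DCE maps — which an affine mapping would not
  produce.  This skew matters physically: it sets where transvascular
  dilution and drug drainage act.
* **Ktrans**: monotone in the same latent (hot spots are also leaky),
  0.02–2.42 × the configured mean (default 5e-3 s⁻¹), keeping the Eq-derived
  S0/V within plausible bounds.
* **Intracellular fraction**: mapped onto (0.5808, 0.999) but capped at the
  closure-feasible ceiling (1−ε_BL−0.02)/(1+r) ≈ 0.85 — the configured upper
  endpoint 0.999 is unreachable under the closure with r = 0.154, an
  inconsistency resolved in favor of the closure.  Its latent is
  anti-correlated with the vascular latent (default ρ = −0.5): densely
  cellular regions are poorly perfused, which the source observations state
  directly ("low tissue porosity and microvascular density" where cell
  density is high).  The ECS fraction follows from the closure (floor 0.02).
* **Leakage constant**: independent field on (1e-5, 3e-4) s⁻¹.

Normal tissue is homogeneous (ε_BL 0.01, ε_ECS 0.20, Ktrans 20% of the
tumor mean, λ_tr 5e-5 s⁻¹, T10 1.0 s; tumor T10 1.4 s).  The AIF is a
delayed double-exponential bolus c_b = A1 e^{−m1 τ} − A2 e^{−m2 τ}
(defaults A1 = A2 = 6 mM, m1 = 0.008, m2 = 0.05 s⁻¹, arrival 10 s; peak
~3.6 mM at ~54 s), whose mode has a closed form used as a test oracle.
Optional signal noise is additive Gaussian (a stated simplification — real
MR magnitude noise is Rician).

What passing tests therefore show: the quantification chain inverts its own
forward physics exactly, and the transport model reproduces analytic limits
and the qualitative treatment patterns *given* tissue fields with the
configured statistical structure.  They do not show robustness to real MR
artifacts (motion, B1, Rician noise, partial volume) or to tumor geometries
beyond smooth ellipsoids.

## Study conditions

The comparison study follows the source protocol: infusion at 3.0 µL/min
for 3 days; inlet concentrations 5.15e-3 M TMZ (plain or encapsulated) and
7.26e-5 M BEV; catheter a single 0.9 mm track entering along +z with a
rigid no-flux shaft and the tip at the densest-microvasculature tumor cell
(site-sensitivity sweeps move the tip to the extreme plasma-fraction and
intracellular-fraction cells).  Outcome measures are evaluated over the
tumor mask on Day 3: ECS-volume-weighted average free-drug concentration,
distribution non-uniformity NUN, and effective volume V_eff (tissue volume
at or above the LD90 of 3.9e-5 M); distance courses bin cells into
sphere shells of one in-plane cell width.

Default problem size: 30³ cells (1.5 mm voxels), ~4,300 macro steps of
≤60 s per regimen — chosen so the full four-regimen study plus both
site sweeps completes in well under an hour on one core while keeping the
tumor ~15 cells across; halving the voxel changes Day-3 metrics by a few
percent and no ordering.

## Known limitations

* A result established by this implementation: with the tabulated drug
  parameters, plain drug outlives liposomal drug wherever drainage is
  active, because protein binding and cell partitioning shelter most free
  drug from the blood (only the ECS free fraction drains) while liposomes
  leak at P_TV·S/V unprotected.  Liposomal delivery wins on accumulation
  only where S/V ≲ 2e3 m⁻¹.  Infusing at the densest-vasculature site,
  the liposomal arms therefore do not out-accumulate their plain
  counterparts here, although they do distribute more uniformly and cover
  a larger kill volume with BEV.
* No tissue deformation, backflow along the catheter, oedema, lymphatics,
  liposome cell uptake, cell-kill pharmacodynamics, or staggered infusion
  schedules; κ is held fixed as ε_ECS grows.
* The tip-cell Dirichlet inlet makes near-tip concentrations one-cell
  resolved; infusion-site magnitudes are reported only through
  grid-robust measures.
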