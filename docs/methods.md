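# Methods

## Physical model

A uniformly charged plane (surface charge density σ, C/m²) in a
symmetric 1:1 electrolyte carries a diffuse double layer with screening
constant κ = √(2 N_A e² I·10³ / ε_w ε_0 k_B T).  A neutral particle is
modelled as a homogeneous sphere of radius a (identified with the
polymer hydrodynamic radius R_h) and interior permittivity ε_p = 10 ε₀,
a conventional value for a water-poor polymer interior.  Two repulsive
free energies are computed as functions of the sphere-center distance z
from the plane of charge.

**Dielectrophoretic energy (closed form).**  The point-dipole
dielectrophoresis force F = 2π a³ ε_w CM ∇E², with CM the
Clausius–Mossotti factor (ε_p−ε_w)/(ε_p+2ε_w), is integrated along z
using the linearized (Debye–Hückel) field E(z) = σ/(ε_w ε_0) e^(−κz),
giving E_D(z) = K_D e^(−2κz) with K_D = −2π a³ CM σ²/(ε_w ε_0).  For
ε_p < ε_w this is repulsive and scales as a³σ².

**Counterion-pressure energy.**  The linearized osmotic excess pressure
Π(z) = σ²/(2 ε_w ε_0) e^(−2κz) is integrated over the sphere's excluded
volume by 1-D Gauss–Legendre quadrature over the slab decomposition of
the sphere (64 nodes, doubled until the result changes by < 0.1%).  For
an exponential pressure this equals K_H e^(−2κz) with
K_H = V_sphere Π(0) g(2κa), g(x) = 3(x cosh x − sinh x)/x³, so the
log-slope is exactly −2κ and the small-sphere limit is V·Π(z).  An
alternative pressure model (van't Hoff on the full ion excess with the
Grahame surface potential) is available for the order-of-magnitude
chain.

**Depletion distance.**  The depletion layer is taken to extend to the
distance d where E_D + E_H = 1 k_BT, found by bisection on the
log-linear interpolant (0.01 Å).  The polymer-free gap is d* = d − R_h.
With a = 7 Å, σ = 0.35 C/m², 0.1 M salt this gives d ≈ 20.8 Å.

### Two conventions for the double-layer amplitude

The closed-form energies use the Debye–Hückel amplitude σ/(ε_w ε_0 κ)
for the potential, which keeps the σ² prefactors exact within linear
response.  The order-of-magnitude estimates (ion excess, van't Hoff
pressure, field gradients) instead carry the full nonlinear Grahame
surface potential decayed as e^(−κz) ("linear_decay" mode): at
σ = 0.35 C/m² and 0.1 M this reproduces an ion excess of ≈ 0.68 M one
Debye length out and a ≈ 1.7 MPa van't Hoff pressure.  The exact
nonlinear Gouy–Chapman profile ("nonlinear_gc") is also provided; both
yield ∇E² in the 10²⁴–10²⁵ V²/m³ range at 5–15 Å.  Temperature default
is 298.15 K and ε_w/ε₀ = 78.5; CODATA values for e, k_B, N_A, ε₀.

## Maxwell-stress numerical backend

The finite-size/ionic-screening corrections neglected by the classical
point-dipole expression are computed by solving the axisymmetric
linearized Poisson–Boltzmann equation ∇·(ε∇ψ) = ε_w ε_0 κ² s ψ on a
cylindrical (r, z) finite-volume grid: ε = ε_p and s = 0 inside the
sphere (the coil excludes ions), ε = ε_w and s = 1 in the solvent,
surface-charge flux condition at the wall, the unperturbed 1-D profile
as the far-field Dirichlet condition (domain padding 2.5 κ⁻¹), and
harmonic-mean face permittivities with a volume-fraction-smoothed
interface.

The total force on the sphere is the surface integral of the combined
Maxwell + osmotic stress, T = ε_w(EE − ½E²I) − ½ε_w ε_0 κ²ψ² I, which
is divergence-free in the linearized solvent, evaluated on a
sphere-concentric surface just outside the dielectric interface by
Gauss–Legendre quadrature in cos θ.  Subtracting the unperturbed
counterion-pressure force 2κE_H(z) isolates the dielectrophoretic part;
all polarization and ion-exclusion corrections are thereby attributed
to E_D, matching the convention in which the full treatment *exceeds*
the classical expression.  E_D(z) follows by integrating the force to
infinity (trapezoid over the solved range plus an exponential 2κ tail).

The smoothed dielectric interface limits the field to first-order
accuracy in the grid spacing h, so forces are Richardson-extrapolated
from a step-halved pair (default h = a/12); an optional refinement loop
continues halving until the extrapolated force changes by < 2%.
Validation: in the weakly screened small-sphere limit (κa = 0.2) the
backend agrees with the closed form within 10%; in the experimental
regime (κa ≈ 0.73, σ = 0.35 C/m²) it exceeds it by ~1.5× with a decay
constant within ~1.5% of 2κ; the force is exactly even in σ.

## Reflectometry forward model

The interface is described in composition space: silicon half-space,
native oxide, substrate–bilayer water gap, inner headgroups, combined
acyl chains, outer headgroups — each an error-function-edged box.
Adjacent boxes share edge positions and roughness, which makes
over-filling impossible; peak occupancies follow from molecular volumes
and the area per lipid (72 Å²), so the integrated bilayer volume is
invariant under thickness changes (the "constant bilayer volume"
constraint holds by construction).  Scattering lengths and molecular
volumes ship as a small editable table with literature defaults; the
polymer nSLD is fixed at 0.7×10⁻⁶ Å⁻².

The polymer volume fraction is Boltzmann-suppressed by the theoretical
interaction energy: c(z) = c∞ exp[−E₀ e^(−2κ(z−z₀))], scaled by the
space left by the molecular components; the same expression is applied
below z₀, where it vanishes rapidly.  Solvent fills all remaining
space, and the backing half-space is the bulk *solution* (solvent plus
dissolved polymer at c∞).  The exclusion distance — where the polymer
density reaches half its bulk value — has the closed form
z_half = z₀ + ln(E₀/ln 2)/(2κ), reported relative to the hydrophobic
interface (outer tails/headgroup boundary); E₀ < ln 2 means the
crossing does not exist and is flagged as below resolution.

Reflectivity: the continuous nSLD profile is micro-slabbed at 0.5 Å
(1 Å inside the fitting loop) and fed to the Parratt recursion; all
roughness is realized in profile space, while the kernel also supports
Névot–Croce factors for generic slab models.  A numba-compiled kernel
is used when importable and is verified against the pure-numpy
recursion; the test suite additionally checks both against an
independent Abeles transfer-matrix implementation to 10⁻¹⁰.
Resolution smearing is a Gaussian in Q with σ = ΔQ/2.355, applied as a
row-normalized convolution matrix from an oversampled logarithmic grid
onto the measurement grid (endpoints handled by the renormalization).

## Reduction and fitting

Counts reduce as R = (I − I_B)/I₀ with I_B the mean of the two
bracketing off-specular intensities; Poisson variances (with a
one-count floor) add in quadrature, and negative net intensities are
retained.  The joint fit shares structural parameters across contrast
conditions with one free solvent nSLD per contrast, under uniform box
priors (thicknesses within 0–60 Å ranges, E₀ ∈ [0, 20] k_BT, κ⁻¹ fixed
by the known ionic strength).  A trust-region least-squares pass finds
the maximum a-posteriori point and its Gauss–Newton covariance; an
affine-invariant ensemble sampler (differential-evolution and snooker
moves) started on that Laplace ellipsoid explores the posterior.
Convergence is monitored with the split-chain potential scale reduction
statistic (flagging threshold 1.05); short chains started from the
Laplace approximation can carry a larger statistic while the marginal
intervals are already stable, so the flag is reported rather than
silently discarded.  Derived quantities — above all the exclusion
distance — are computed per posterior sample; intervals are central
percentiles (68/95%).  E₀ and z₀ are individually degenerate along a
ridge, but the exclusion distance is the stable combination, which is
why it is the reported quantity.

## Profile post-processing

Mass fractions convert to free energy via E(z) = −ln[m(z)/m(∞)], with
m(∞) averaged over the outermost 20% of the grid by default; zero bins
are censored.  The charged-minus-neutral difference isolates the
charge-induced repulsion.  ΔE is fitted as A e^(−z/λ) by weighted least
squares on log ΔE (weights (value/σ)², i.e. inverse variance of the
log; uniform when uncertainties are absent or exact), over a window
from R_h + 2 Å (excluding the contact regime where the exponential form
fails) to the first bin below 0.1 k_BT; non-positive values are dropped
with a warning, and fewer than five surviving points is an error.  The
1 k_BT distance and its uncertainty follow from the fit covariance.
The size-scaling exponent is the slope of log ΔE(z_eval) against
log R_h over ≥ 3 molecular weights.

## Synthetic data: what it emulates and what it does not

**Reflectivity counts.**  The instrument grid spans 0.008–0.379 Å⁻¹
with bin widths 2.5% of the bin center.  Expected counts are the
smeared model reflectivity times an incident intensity
I₀(Q) = 10⁶·(1 + (Q/0.05)⁴) — emulating the longer counting times at
high angle that keep relative errors roughly constant — plus an
incoherent background of 5×10⁻⁷ of the incident beam, all
Poisson-sampled from a seed-derived generator; bracketing off-specular
background curves are emitted for the reduction step.  Two contrasts
are generated: the D₂O polymer solution, and a polymer-free
90:10 D₂O:H₂O control whose bulk nSLD matches the polymer solution.
The generator does not emulate instrument footprint/gravity effects,
off-specular structure, or time-dependent backgrounds, so passing
recovery tests demonstrate statistical identifiability at realistic
count levels, not robustness to those instrument systematics.

**Ground truth.**  Bilayer defaults: 15 Å oxide, 4 Å water gap, 9 Å
headgroups, 28 Å acyl region, coverage 0.95, roughness 2.5/3 Å;
110 mM ionic strength (100 mM KCl + 10 mM buffer) and 9.1 wt% PEG600
(10:1 by weight), giving a bulk volume fraction of 0.089.  E₀ is taken
from the sphere-interaction theory for the preset's surface charge
(half-charged mixed bilayers), or 1.5 k_BT as a steric residue for the
neutral preset.  The plane-of-charge position z₀ is treated as an
effective parameter: the sharp profile model does not resolve the
polymer's own size, which in real fits is absorbed by z₀ moving outward.
When a target exclusion distance is requested (the 30 Å standard
fixture), z₀ is placed to realize it at the theoretical E₀ — keeping
E₀ inside its prior range.

**Profile pairs.**  The neutral-membrane baseline is a smoothed step at
the coil radius; the charged profile multiplies it by
exp[−A e^(−2κz)] with A = e^(2κd) so the 1 k_BT distance of the
difference is exactly the tabulated depletion distance for that
molecular weight (16–28 Å for 600–6000 Da).  Bin noise is Gaussian with
σ = 0.015·√m in bulk units — counting-statistics-like, at the percent
level appropriate to microsecond-scale sampling — on a 1 Å grid to
100 Å (profiles must extend a few decay lengths past the largest d so
the bulk window is uncontaminated; tall simulation boxes provide this
in practice).

## Numerical choices and limitations

* Depletion-distance bisection tolerance 0.01 Å; quadratures doubled
  until < 0.1% change; stress-tensor refinement rule 2%.
* The fitting loop evaluates the forward model at 3× oversampling of
  the measurement grid and 1 Å micro-slabs; the generator uses 4× and
  0.5 Å.  The residual model discrepancy is ~χ²/point 1.1–1.6 on
  synthetic data and does not bias the exclusion distance measurably.
* The recovery study (20 noise realizations, 24 walkers × 220 steps
  after a least-squares start) is sized for a workstation-scale run;
  production fits should use longer chains (the defaults in
  `joint_fit`) and check the convergence flag.
* Non-goals: asymmetric/multivalent electrolytes, Stern layers, charge
  regulation, image charges, polymer conformational degrees of freedom,
  AC dielectrophoresis, off-specular/polarized neutron effects, and
  running or parsing molecular-dynamics trajectories.
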