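# Methods

## Reduced-order trans-stenotic pressure model

The pressure field along an axisymmetric vessel carrying steady flow `Q`
is computed from a 1-D momentum balance rather than a 3-D Navier–Stokes
solve. Three physically distinct contributions are accumulated along the
centerline grid:

1. **Distributed viscous friction** (Poiseuille closure):
   `dp = 8 μ Q / (π r(z)^4) dz`, integrated by the trapezoidal rule on the
   geometry grid.
2. **Bernoulli area term**: `(ρ Q² / 2) (A(z)^-2 − A(0)^-2)` — reversible
   acceleration into the throat and recovery beyond it.
3. **Irreversible expansion loss** (Young/Tsai-type):
   `Δp_loss = K_t (ρ/2) (1/A_throat − 1/A_ref)² Q²` with `K_t = 1.52`
   (configurable), accumulated linearly over the diverging half of the
   stenosis (throat → distal edge) and zero proximal to the throat. The
   linear localization is a modeling choice; only the total loss is
   constrained by the loss coefficient.

Assumptions: steady flow (no pulsatility), rigid no-slip wall, zero body
force, incompressible Newtonian blood with ρ = 1046 kg/m³ and
μ = 0.004 Pa·s. Mass conservation is exact by construction
(`u_mean = Q/A`). Wall shear stress uses the Poiseuille wall closure
`τ_w = 4 μ Q / (π r³)`, so the throat-to-inlet WSS ratio is
`(1 − degree)^-3`.

The viscous term has a closed-form oracle in a uniform tube
(Hagen–Poiseuille, `Δp = 8 μ L Q/(π R⁴)`); the solver matches it to
well below 0.1% at ≥ 200 grid points, and the error against an adaptive
quadrature oracle decreases monotonically under grid refinement. The
solver refuses nonphysical regimes (pressure ≤ 0 anywhere) with a
diagnostic rather than returning negative pressures.

### CAFA indices

* `CAFA_p = mPd / mPa`: `mPa` is the solved pressure at the inlet
  (proximal reference); `mPd` is interpolated 3 cm (configurable) distal
  to the stenosis edge, mirroring wire placement. The inlet reference
  pressure defaults to 100 mmHg (13 332 Pa); it is a required, logged
  configuration value because `CAFA_p` depends on it.
* `CAFA_v = Q_S / Q_N`: each flow solves
  `Δp_vessel(Q) + R_dist·Q = p_perf` by Brent root finding on a bracket
  whose upper end is the uniform-tube Poiseuille flow (an upper bound on
  any resistive configuration). The default distal bed resistance
  (3.15 × 10⁹ Pa·s/m³) is chosen so a healthy 2.5 mm ICA at 100 mmHg
  carries ≈ 4.2 ml/s, a typical mean ICA flow.

Both indices are strictly decreasing in stenosis degree at fixed
boundary conditions; this monotonicity is enforced by test sweeps over
degrees {0, 0.3, 0.5, 0.7, 0.9} (at 0.5 ml/s, a flow low enough that the
90% lesion remains in the physical regime at the default inlet pressure).

## DSA-derived inlet boundary

The volumetric flow rate is the opacified lumen volume difference between
two frames divided by the elapsed time, `Q = ΔV/Δt`; the inlet velocity is
`Q/(π r(0)²)`. The default frame pair spans the first frame with contrast
to the last frame before bolus exit. The opacified volume is treated as
cumulative; under plug flow, increment-based and cumulative bookkeeping
are equivalent.

## Synthetic patient generator

The generator is first-class, tested code; its defaults define the
conditions used throughout the tests and the acceptance script.

* **Geometry**: cosine-shaped constriction
  `r(z) = r0[1 − (d/2)(1 + cos(2π(z−z_c)/L_s))]`, a standard smooth
  stenosis profile; severity `d` follows NASCET (`1 − r_min/r_ref`).
  Default case: r0 = 2.5 mm, d = 0.70, lesion centered 20 mm from the
  inlet, 20 mm long, 100 mm vessel.
* **DSA bolus**: plug flow of the contrast front — `V(t) = Q·t` until the
  front exits (then flagged truncated). This makes the frame-based flow
  estimate exact, which is the point: it isolates estimator errors from
  transport-model errors. Contrast dispersion, mixing and pulsatile
  dynamics are deliberately not modeled. Default Q = 4.2 ml/s, 10
  frames/s. Frame rate and the frame pair are fully configurable since
  acquisition protocols vary.
* **ASL signals**: the exact kinetic forward model of the quantification
  chain (`ΔM_i = 2 α M0 (f/6000) B_i(δ)/(λ R1a)`) plus additive Gaussian
  noise scaled to the mean noiseless |ΔM| (default 2%). Because forward
  and inverse share the kinetic factor, the noiseless round trip is exact
  to numerical tolerance — a consistency check, not evidence about real
  scanner data (background suppression, motion, partial volume are not
  emulated).
* **Pressure wire**: the solved profile sampled along a pull-back
  trajectory plus additive Gaussian pressure noise (default 1% of the
  proximal reference), expressed as Pd/Pa.

All stochastic generators take explicit integer seeds and are
bit-reproducible; there is no hidden global random state.

## Multi-delay pCASL quantification

Constants (3 T defaults): PLDs w = 1.0/2.0/3.0 s, labeling duration
τ = 1.5 s, tagging efficiency α = 0.8, partition coefficient
λ = 0.9 g/ml, blood R1a = 0.61 s⁻¹ (0.72 at 1.5 T). The per-delay CBF is
scaled to ml/100 g/min by the explicit factor 6000 (from ml/g/s).

The WD→ATT conversion is implemented as numerical inversion (Brent) of
the forward map `WD(δ) = Σ w_i B_i(δ) / Σ B_i(δ)` on
δ ∈ [min w, max w + τ). The forward map is verified monotone on this
bracket before inversion. WD values at or below the all-arrived plateau
(δ ≤ min w) are not identifiable; they are returned censored-low at
δ = min w (flagged, not silently clamped), and symmetrically censored-high
at the upper end. Voxels with zero total signal propagate NaN; per-delay
CBF is masked where the decay factor falls below 10⁻¹⁰.

### Regional report and misery-perfusion screen

The regional report takes per-territory, per-side per-PLD CBF and ATT,
computes the per-side final CBF (mean over delays), and the left–right
percentage difference `Δ% = (L − R)/R × 100`. Values are reported at 2
decimals; the final-CBF Δ% is computed from the 2-dp-rounded per-side
finals, matching the tabular convention in which readers verify Δ%
against the printed finals. Δ% is signed by default with an
absolute-value display option.

Misery perfusion is flagged when final CBF < 35 ml/100 g/min, ATT >
7.89 s, or |Δ%| > 10 (the normal left–right variation band). The screen
is conservative: it uses the lower of the two side finals and the longer
ATT per region.

## Agreement analysis

Simulated and wire pull-back curves are paired one-to-one at n = 18
positions uniform on their common axial interval (linear interpolation in
z; the source pairing rule beyond "one to one" is unspecified, so uniform
arc-length spacing was chosen). Statistics: Pearson r with a two-sided
t-distribution p (n − 2 df), paired t-test (n − 1 df), and Bland–Altman
bias with sample SD (n − 1 denominator) and 1.96·SD limits of agreement.
Degenerate cases are flagged explicitly: identical series give t = 0,
p = 1; a constant nonzero shift has zero-variance differences and sets an
infinite-t flag.

## Problem sizes and numerical choices

Tests and the acceptance script run on desk-scale problems: 200–800-point
geometry grids, 18-point pull-backs, 1,000-voxel ASL recovery
experiments, 16×16-voxel regional blocks. Tolerances: Poiseuille oracle
< 0.1%; noiseless ASL round trip < 10⁻⁶ relative; noisy recovery (2%
signal noise) median |CBF error| < 5% and median |ATT error| < 0.1 s;
flow recovery < 0.1%; sim-vs-wire r > 0.8 and |bias| < 0.02 at 1%-of-mPa
wire noise.

## Known limitations

* The 1-D reduction cannot represent asymmetric lesions, curvature,
  bifurcations, turbulence or fluid–structure interaction; the expansion
  loss coefficient K_t subsumes all post-stenotic dissipation.
* Steady flow only: the pressure ratio of a pulsatile system averaged
  over the cycle differs from the ratio at mean flow because the loss
  terms are nonlinear in Q.
* The synthetic ASL generator shares its kinetic model with the
  quantifier, so recovery tests validate the inversion machinery, not
  the biophysical fidelity of the model to tissue.
* The WD→ATT relationship is the self-consistent inversion of the
  implemented kinetic factor; published lookup-table conversions may
  differ in constants.
* Sub-voxel region masks, atlas segmentation and partial-volume effects
  are out of scope; regional inputs are user-supplied means.
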