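# Methods

This note documents the model equations as implemented, the numerical
choices, the synthetic-data generator's study conditions, and the known
limitations — in particular what passing the test suite does and does not
establish about real laryngeal data.

## Structural model

The fold cross-section is a plane-strain, linear, isotropic viscoelastic
body meshed with 3-node triangles (consistent mass).  The constitutive
operator is `C(E, ν) = μ Ĉ(ν)` with shear modulus `μ = E / 2(1+ν)`;
Kelvin–Voigt damping replaces `μ` with `μ + η d/dt`, which at the element
level makes the damping matrix `D_e = (η/μ_e) K_e` — damping therefore
shares the stiffness sparsity and scales with the *viscosity*, not the
modulus, of each layer.  The mesh is a four-layer "modified M5" outline
(body core, ligament, superficial lamina propria, 0.3 mm epithelium) whose
polygons ship in `data/m5_geometry.json`; layer bands are inward offsets of
the air-exposed surface, so the compliant cover wraps the inferior ramp,
medial surface and superior face while the stiff body fills the core.

Units: all mechanics run in a self-consistent mm–g–ms system (force in N,
stress in MPa); public APIs use kPa, kg/m³, Pa·s, mm, ms.

Poisson ratio is fixed at 0.4995.  Linear triangles are known to stiffen
(volumetric locking) this close to incompressibility; the effect is part of
the model family being calibrated, and identical in the generator and the
fitted model, so synthetic-twin recovery is unaffected.  Quantitatively it
reduces static compliance by roughly 3x relative to ν = 0.3 at these meshes.

### Contact and medial precompression

A rigid hemilaryngeal plane sits at `x = 8.4 mm`.  After every time step any
node beyond the plane is projected back onto it exactly and its x-velocity
zeroed (perfectly inelastic wall; configurable).  The initial medial
compression `m` shifts the whole reference configuration (including the
support) medially and solves the static problem.  Two equivalent routes are
implemented: the literal incremental loop (1e-4 mm shift steps with 1e-4 N
penalty increments on crossing nodes) and an active-set contact solve that
enforces non-penetration to 1e-9 mm.  The active-set equilibrium is the
limit of the penalty procedure (a regression test asserts the two agree),
so the inference hot path runs the active-set solve alone.

### Time integration

Newmark average acceleration (γ = 1/2, β = 1/4), unconditionally stable for
the linear system, with `dt = 0.01 ms`.  The step treats the surface load
evaluated at the beginning of the step as the end-of-step force; initial
acceleration is computed consistently from the precompressed state with the
flow switched on.  For linear steps without contact the discrete energy
identity holds to machine precision (tested).  The contact projection
breaks the Newmark triplet consistency at collision steps: projection jumps
and the subsequent stale-acceleration work largely cancel, leaving a net
wall interaction of order 10 % of the gross fluid work over steady collision
cycles (window dependent, tested under 20 %).

## Flow models

Both models act on the glottal channel `z ∈ [−3.6, 0] mm`, discretized at 50
uniform stations.  The channel gap is the distance from the deformed
surface to the contact plane, evaluated at material (reference) z
coordinates — consistent with the small-displacement kinematics — and the
2D width-to-area convention is `A = gap × depth` with `depth = 14 mm`.
Surface loading: station pressures are interpolated to surface-edge
endpoints and integrated consistently (1/3–1/6 splitting); the surface below
the channel inlet carries `p_sub` (subglottal loading of the entrance ramp)
and above the outlet `p_sup`.  During (partial) closure the stations carry
`p_sub` upstream of the first contacting station, zero in the contact zone
and `p_sup` beyond it; gaps below 1e-6 mm count as closed.

Bernoulli: `p = p_sub − (p_sub − p_sup)(A_sep/A)²` with
`A_sep = r_sep A_min`; stations upstream of the minimum always use this
branch, and separation is the first station at or downstream of the minimum
with `A ≥ A_sep`, after which `p = p_sup`.

Viscous: steady continuity (`q = wA` constant) plus the momentum balance in
which the separation-loss stress reduces advection to `χ ρ_f w w′`
(`χ = 1` up to the minimum-area station, `χ_min = 0.2` beyond), duct
friction `−2 μ_f (S/A)² w` with `S = 2·depth` (high-aspect-ratio duct), and
effective area `A = α(z) A₀(z)` with the quadratic vena-contracta correction
(0.75 at the outlet, 1.0 at the inlet).  For a given `q` the pressure
integral is exact in the advection part and trapezoidal in the friction
part, so the outlet condition `p(z_out) = p_sup` is solved by bracketed
Brent iteration on `q` (residual < 1e-8 kPa); the quasi-steady reduction
drops the `∂/∂t` terms, whose transit time is far below the structural time
scale.  In strongly divergent instants (minimum at the inlet) full `χ_min`
recovery can make the outlet condition unreachable for every flow rate; the
recovery constant is then capped at the largest solvable value
(`effective_chi_min`), which is also the physically sensible statement that
a separated jet cannot recover more pressure than the downstream boundary
admits.  The compiled simulation kernel solves the same quadratic-in-`q`
equation in closed form; a property test pins it to the module solver.

## Synthetic observations (study conditions)

The generator replaces unavailable high-speed-video segmentations.  Nominal
truth: `E_body 11.8, E_slp 0.6, E_lig 2.0, E_epi 45.0 kPa` (epithelium and
`ν`, `p_sup = 0` fixed in inference), `ρ_b = 1070 kg/m³` (soft-silicone
density), `η = 0.01 Pa·s`, `m = 0.4 mm`, and subglottal pressures
`0.910, 1.001, 1.092, 1.183 kPa`.  The geometry's cover-band thicknesses and
the nominal `η` were chosen once so the fold self-oscillates with full
phonatory collision at all four pressures — the qualitative regime of the
silicone experiments — with peak widths of 0.5–0.9 mm, making the 1 mm²
area-noise σ roughly 10–20 % of the peak area.  Waveforms are reported at
0.25 ms sampling (a 4 kHz video-rate analogue); noise is unbiased Gaussian
in width units (`σ_area / depth`) with clipping at zero width recorded in
the metadata (the only bias, active during closed phases).

The realized dynamics oscillate near 40 Hz with genuine cycle-to-cycle
variability (±5–8 % in peak and period, robust to halving `dt` and doubling
the station count): collision oscillators are well known to exhibit such
jitter.  Consequently the waveform is near- but not strictly periodic
(autocorrelation peak ≈ 0.8 at the fundamental).

## Inference

Prior-as-proposal importance sampling: weights ∝ likelihood, normalized with
a log-sum-exp shift (invariant to constant offsets), multinomial resampling
from a seed stream decoupled from the prior draws, posterior summaries from
the weighted ensemble, and `n_eff = 1/Σw²` reported.  Failed forward runs
(blow-ups, shooting failures) receive zero weight and are counted.
Registration: simulated and observed waveforms are phase-aligned by the best
circular cross-correlation lag on the observation grid before computing
residuals.

Likelihood whitening.  With the exact 1 mm² noise σ, an iid Gaussian
likelihood over a video-rate window is so sharply peaked relative to the
model's chaotic cycle jitter that plain importance sampling degenerates
(`n_eff → 1`) at any affordable ensemble size: the jitter acts as un-modeled
error exactly like the model error that motivates σ inflation in this kind
of fitting.  The scaled-down studies therefore keep the *data* noise at
1 mm² but evaluate the likelihood with an inflated σ — 4 mm² for
matched-model recovery, larger (14 mm²) for mismatched-flow-model fits where
model error dominates — calibrated once for ensemble health and then used
unchanged.  Default priors follow broad plausibility ranges (moduli ±50 %,
`p_sub` ±20 %, `ρ_b` 900–1200 kg/m³, `η` 0–10 Pa·s, `m` 0.2–0.6 mm, `r_sep`
1.0–1.6); the recovery experiments use narrowed priors (±10 % moduli) as
appropriate for a few-hundred-sample ensemble.

## Scaled-down experiment sizes

The full-scale study (15 000-sample ensembles on a fine mesh) is far beyond
a single desk run; the shipped experiments use: recovery — ~300-element
mesh, 100 ms simulated (50 ms fitted), n = 500; flow-model bias — ~1000
element mesh, 100 ms, n = 150 per fit; closure check — ~1000-element mesh,
200 ms.  Ensemble health and posterior widths at these sizes are reported by
the tests themselves; uncertainties shrink and estimator noise falls roughly
as `1/√n_eff` as the ensemble grows.

## Flow-model bias experiment: observed behavior

Fitting Bernoulli models with fixed `r_sep` to a viscous-model observation
shows oscillation amplitude decreasing monotonically with `r_sep`
(`r_sep = 1` strongest: no opening-phase outlet suction opposing the
opening).  The 1D viscous model — with its literal `p(z_in) = p_sub` inlet
condition (no upstream kinetic-energy drop) and vena-contracta-enhanced
Bernoulli dip — drives the fold about as strongly as the `r_sep = 1.0`
Bernoulli model.  Fits with `r_sep = 1.6` therefore under-estimate the
moduli robustly (≈ 0.75–0.85 of truth), while fits with `r_sep = 1.0` land
near unity rather than above it: in this twin the viscous truth sits at the
strong edge of the swept separation-ratio range, not mid-range.  A system
whose effective separation ratio falls mid-sweep would show the classic
over-then-under pattern; this one shows only the under-estimation half, and
the corresponding acceptance test records that outcome.

## Known limitations

- 2D plane strain: anterior–posterior tension and 3D modes are absorbed
  into effective parameters, not modeled.
- Linear elasticity and linear kinematics at finite (0.5 mm-scale)
  displacements; locking at ν = 0.4995 with linear triangles.
- The contact model is a bare projection; collision forces and Hertzian
  contact mechanics are not resolved, and the projection exchanges a
  non-vanishing net energy with the wall.
- Quasi-steady flow: no flow inertia within a step, no acoustic coupling.
- Passing synthetic-twin recovery demonstrates the correctness and internal
  consistency of the estimation machinery under the model's own dynamics;
  it does not validate the physical model against real laryngeal or
  silicone-fold data, which this package does not ship.
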