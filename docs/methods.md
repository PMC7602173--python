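# Methods

## The membrane-crossing model

The resistance force on a functionalized CNT pulled through a POPC bilayer
is modelled as a discrete-time LTI system from pulling velocity (Å/ps) to
interaction force (N):

    F(z) = H(z) V(z),
    H(z) = k z⁻¹ (1 + a₀z⁻¹)(1 − a₁z⁻¹ + a₂z⁻²)(1 + a₃z⁻¹ + a₄z⁻²)
           / [(1 + b₀z⁻¹)(1 − b₁z⁻¹)(1 − b₂z⁻¹ + b₃z⁻²)(1 + b₄z⁻¹ + b₅z⁻²)].

The mixed plus/minus signs inside the factors are part of the coefficient
convention and are taken literally; `membrane_tf.expand` maps them onto
plain ascending-power polynomials. The structure implies two checkable
facts independent of coefficient values: the impulse response starts
h[0] = 0, h[1] = k (the explicit delay), and the complex pole-pair moduli
are the square roots of the quadratic factors' constant coefficients
whenever their discriminants are negative (they are, for the shipped
coefficient set: moduli √0.9972 and √0.9926).

**Units.** The gain k is interpreted on the (Å/ps → N) unit pair, matching
the velocity scale at which steered-crossing records are taken;
`nanoferry.units` holds the explicit converters (1 Å/ps = 100 m/s). The
sampling period Ts is a free parameter (default 1 ps, the natural pulling
timestep): the coefficients define per-sample dynamics, and every
steady-state design quantity (DC gain, required field products) is
Ts-independent. Filters start from rest (records begin with a zero-input
preamble), and H(1) = 2.2259×10⁻⁷ N per (Å/ps) is the steady resistance
per unit sustained velocity.

## Identification

`fit_pem` estimates (k, a₀..a₄, b₀..b₅) by minimizing the summed squared
output error over one or more records, holding the factored structure
fixed. Two stages:

1. **Equation-error initialization.** The expanded difference equation is
   linear in its polynomial coefficients, so an ARX least-squares solve
   recovers them exactly on noise-free data and approximately otherwise.
   The expanded polynomials are mapped back to the factored form by root
   grouping (two real poles to the first-order factors, conjugate pairs to
   the quadratics). This stage is essential: the output-error surface of a
   model with pole moduli ≈ 0.9986 is multimodal, and plain descent from a
   5%-perturbed start reliably lands in poor local minima (best fit ~25%
   in our experiments, versus ~100% with the staged start).
2. **Damped Gauss–Newton refinement** (Levenberg–Marquardt with Marquardt
   diagonal scaling, finite-difference Jacobian). Accepted iterations never
   increase the cost; the history is stored on the result. The Marquardt
   scaling makes the iterates invariant to a common rescaling of input and
   output, so the fit is equivariant under unit changes.

**Stability** is kept by penalty residuals on pole moduli exceeding
1 − ε plus a factor-wise radial projection of the final iterate. ε = 10⁻⁴
is deliberately small because physically identified membrane models sit
very close to the unit circle. **Identifiability** is diagnosed from the
Jacobian's singular values at the solution; a rank-deficient fit (e.g. a
single constant-velocity record) is flagged `converged = False` with a
warning. The noise model is output-error: no noise polynomial is
estimated.

Fit quality is the normalized-RMS "best fit" 100·(1 − ‖y − ŷ‖/‖y − ȳ‖)
plus the MSE of residuals; both are computed over the concatenated records.

## Synthetic data

`synthetic` emulates the steered-crossing protocol: constant-velocity
records at 1.0–2.0 Å/ps in 0.1 Å/ps steps (11 records), force output from
a known ground-truth model, additive Gaussian noise on the force channel
scaled to a stated fraction of the record's peak |force| (inputs are
exact). Defaults: 2000 samples per record, Ts = 1 ps, a 50-sample rest
preamble so the zero-initial-state assumption holds. All noise comes from
a seeded generator; identical specs reproduce records bit for bit.

Identification inputs are impulse trains whose amplitudes cycle the
protocol velocities. The default spacing (40 samples) is an input-design
choice: dense excitation keeps the response crest factor (peak/RMS) below
5, which matters because measurement noise is referenced to the peak — a
sparse train at the same noise level simply has a worse attainable fit
percentage, not a worse model estimate.

What the generator does **not** emulate: drift, autocorrelated thermostat
noise, velocity-dependent nonlinearity, or any membrane reorganization
between pulls. Passing the recovery tests therefore shows the estimator is
correct and well-conditioned under the modelled noise, not that the LTI
structure captures every feature of real steered-pulling data.

## Inner-cell dynamics and control

Along the field axis, with b_z = αz + c(t):

    z̈ + Cż = κα²z + κα·c(t),   C = 18μ/(ρ_p d_p²) = 1/τ_p,
    κ = Vχ_bead/(m_p μ₀).

The carrier's effective drag diameter d_p defaults to the
equivalent-sphere diameter 2·r_ave (sphere-drag formulas applied to the
tube via its equivalent sphere; overridable). Intracellular flow is zero
by default and gravity/buoyancy is excluded by default — for the default
carrier (100 nm × 10 nm tube, ρ_p = 5000 kg/m³ in water-like cytoplasm,
μ = 10⁻³ Pa·s) the buoyant weight is ~10⁻¹⁹ N against magnetic forces
approaching 10⁻¹⁴ N at device limits; both switches exist.

These defaults give τ_p ≈ 4.3×10⁻¹⁰ s (C ≈ 2.3×10⁹ 1/s): the velocity
relaxes essentially instantly, making the raw ODE very stiff. The
open-loop integrator therefore switches from explicit RK45 to a stiff
method (LSODA) whenever C·dt > 10, and a blow-up check rejects diverged
trajectories with advice to reduce dt. Open-loop accuracy is verified
against the exact matrix-exponential solution of the constant-offset
linear ODE.

**Controller.** Feedback linearization picks

    c(t) = (Cż − κα²z + z̈_d − m₁ė − m₂e)/(κα),

cancelling the plant so the error obeys ë + m₁ė + m₂e = 0 — stable for any
m₁, m₂ > 0, independent of (C, κ, α). The cancellation happens inside the
right-hand side, so the closed loop is *not* stiff and integrates with
RK45 at rtol 10⁻¹⁰ (the cancellation's floating-point residual, ~10⁻¹⁶·Cż,
is far below the retained terms for all tested scenarios). Full-state
feedback is assumed (no observer). α = 0 is rejected as singular: without
a gradient the magnetic force cannot actuate z.

Metrics: settling time is the first time after which |e| stays within 2%
(configurable) of |e(0)| — 0 if it never leaves the band, NaN if it never
settles in the horizon; peak field is max |αz + c(t)|. Gain sweeps use the
critically damped coupling (m₁, m₂) = (2m, m²) so a single speed parameter
m is swept, as in settling-time/peak-field trade-off studies (settling
≈ 5.8/m; peak field grows ≈ linearly in m via the Cż term).

## Field-region design

A crossing deadline t means sustaining v_s = x_membrane/t, hence (by the
model's steady state) force H(1)·v_s, hence field-gradient product
L = μ₀H(1)v_s/(Vχ_bead). The feasible region is
{(b_z, g) ∈ box : L_b ≤ b_z·g ≤ L_u} with the device box
b_z ∈ [0, 2.4] T, g ∈ [0, 0.180] T/m.

**Deadline vs window.** By default each time is read as a deadline
("cross within t"): L_b is the nominal product and L_u the device
capacity (corner product 0.432 T²/m). This makes regions for shorter
deadlines strictly nested inside those for longer ones and recovers the
full box as t → ∞. The alternative — a symmetric ±band around the nominal
product, selecting a thin hyperbola strip that crosses in approximately t
— is available via `band=`; note that under the band reading region areas
*grow* with the required product (wider band), so the nesting property
belongs to the deadline reading only. The default membrane thickness is
4.0 nm (typical POPC bilayer) and is surfaced in the region metadata, as
the crossing speeds scale directly with it.

Region areas are computed by grid quadrature (default 500×500, the
boundary hyperbolas are also returned analytically sampled). Emptiness is
exact: the region is empty iff L_b exceeds the box corner product.

## Problem sizes and tolerances

Default experiment sizes: 2000-sample records, 20 identification
replicates, 10-point gain grids, 20-draw oracle comparisons, 500×500 area
grids — all chosen so a full self-consistency run completes in seconds on
one core while leaving the statistical conclusions unchanged at larger
sizes. Key numerical tolerances: carrier volume consistency 10⁻¹²
relative; ODE rtol 10⁻⁸ (open loop) / 10⁻¹⁰ (closed loop, against
closed-form oracles at 10⁻⁴); optimizer relative cost-decrease threshold
10⁻¹²; stability margin ε = 10⁻⁴.

## Known limitations

* The LTI membrane model is a small-signal description around the recorded
  pulling regime (1–2 Å/ps); extrapolating its DC gain to the mm/h speeds
  of second-scale crossings assumes linear behaviour far below the
  recorded range.
* Motion is 1-D along the field axis; off-axis field components and 3-D
  trajectories are out of scope.
* Brownian forcing is not modelled; at 10 nm scales thermal motion is
  non-negligible in reality and would appear as a disturbance the
  controller must reject.
* The controller assumes perfect, instantaneous state measurement.
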