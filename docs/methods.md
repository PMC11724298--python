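# Methods

## The two-state model

A 60-bp duplex held between two beads hops between B-DNA and the
overstretched S-form inside a narrow force window around the equilibrium
transition force `F_tr` (the force at which both states are equally
probable). The package models the system with four ingredients:

1. **Linear elastic branches.** Within the 55–72 pN operating window both
   states' force–distance relations are straight lines; no worm-like-chain
   or freely-jointed-chain elasticity is used because no analysis step ever
   leaves this window. The branch geometry is parameterized by the B-branch
   line `F = k_b (λ − λ_ref)` (slope defaulting to the trap stiffness: the
   molecule plus handles are far stiffer than the 0.1 pN/nm trap, so the
   effective stiffness is the trap's) and by the horizontal offset of the S
   branch, `x_S(F) − x_B(F) = ΔX(F)`.

2. **Deterministic end fraying.** The extension gained in one transition
   shrinks linearly with force, `ΔX(F) = ΔX_tr − m (F − F_tr)` with
   `m = 1 nm/pN` by default, floored at zero: higher force frays more base
   pairs off the free duplex ends before the cooperative transition, and
   ~4 bp/nm fewer base pairs participate. Fraying is treated as an
   instantaneous function of force with no kinetics of its own; the
   experiment does not resolve fraying dynamics. A consequence worth noting:
   because the S branch carries the frayed offset, its slope in the
   force–distance plane is `k_b/(1 − k_b·m)` (≈ 0.111 for the defaults),
   slightly steeper than the B branch, and the branches *converge* at high
   force — above ~69 pN (defaults) they are closer than the noise and no
   transition can be resolved there.

3. **Bell–Evans rates pivoted on `F_tr`.**
   `k_B→S(F) = k_tr e^{+(F−F_tr) X_B→TS / k_BT}`,
   `k_S→B(F) = k_tr e^{−(F−F_tr) X_S→TS / k_BT}`.
   Using (`k_tr`, `F_tr`) as the anchor instead of zero-force prefactors
   keeps the identifiable parameters in the model; zero-force rates are
   derived (and reported as extrapolations only). With
   `X_B→TS + X_S→TS = ΔX_tr` enforced, the rate ratio reproduces the
   two-state occupancy `P_S(F) = 1/(1 + e^{−ΔX (F−F_tr)/k_BT})` exactly.

4. **Thermal scale.** `k_BT = 4.089 pN nm` at the 23 °C working temperature
   (the experiments quote 23 ± 1 °C); 1 k_BT = 0.59 kcal/mol.

### Construct presets

Named presets carry the published per-construct equilibrium and kinetic
values ("Unmodified", "1tC", "2tC", "2tC-Stack", "3tC", the purine-rearranged
variants and the 200 nm/s / 150 mM rows). Two reconciliations are applied
when building a simulation ground truth from a preset:

* The two transition-state distances are rescaled proportionally so that
  they sum exactly to the equilibrium `ΔX` (the published kinetic fit and
  the direct extension measurement differ by ~2%, within their stated
  errors, but the simulator needs a single consistent geometry).
* `k_tr` is not published directly; it is tuned deterministically so that
  the *expected* number of transitions per cycle matches the published mean
  N for that construct at its reference pulling velocity. The expectation
  uses the quasi-equilibrium event rate `2 k_f k_r/(k_f + k_r)` integrated
  along the ramp — exactly linear in `k_tr`, so no iteration is needed.
  The quadrature is accurate to a few percent (the ramp drags the system
  slightly out of equilibrium). For the unmodified duplex at 50 nm/s this
  yields `k_tr ≈ 13 s⁻¹`.

## The simulator

Each stretch/release cycle propagates the two-state system on a fixed
substep `dt = 1e-4 s` (ten times finer than the 1 kHz sampling) with the
exact exponential switching probability `1 − e^{−k(F) dt}`; this is valid
for arbitrarily large rates, and the only discretization error is the force
change within a substep (< 0.002 pN at the default loading rate). The guard
against an unresolvable simulation checks `k·dt` at `F_tr ± 2 pN`, the
region where bistable hopping must actually be resolved — farther out the
state simply saturates within a substep, which the exponential form handles
exactly. Double hops within one substep are neglected; they require both
rates to be large simultaneously, which happens nowhere (the product
`k_f·k_r` is maximal at `F_tr` where both are ~`k_tr`, and
`k_tr·dt ~ 1e-3`).

Cycles start in B at the lower turning force; the state carries over from
stretch to release. Jumps land exactly on the other branch (the stated
"force jump = K_trap·ΔX(F)" picture is the first-order version of this).
Measurement noise is i.i.d. Gaussian on the sampled force; the default
σ_F = 0.2 pN is a fixture choice — the experiment does not report its noise
amplitude — and 0.3 pN is exercised in the tests as a stress case.

What the generator does **not** emulate: bead/handle serial compliance and
hydrodynamics (the branches are ideal lines), drift, force-dependent
calibration errors, stochastic fraying, tether loss, or the melting (B-to-M)
pathway. Passing recovery tests therefore demonstrates estimator
correctness under the stated model, not robustness to instrument artifacts
beyond white force noise.

## Detection

Each half-cycle is processed independently:

1. **Branch fitting.** The low end of the ramp is pure B and the high end
   pure S, so each line is seeded on its pure quartile and refined by
   alternating nearest-line classification (on the median-filtered force)
   and per-class least squares. Only samples well inside their own
   territory (within 0.4 of the local gap) enter the fits: a single
   misclassified sample from the other branch would lever the slope and
   make the extrapolated lines converge. Half-cycles whose classes collapse
   (< 50 samples on a branch, or a gap under 2 nm) are flagged unusable.

2. **Hysteresis state machine.** A flip is accepted when the
   median-filtered force crosses to within 30% of the gap of the *other*
   branch line, confirmed on two consecutive samples. Flips are suppressed
   where the local branch separation falls below a resolvability floor
   (`max(min_jump, 3σ_filtered/(1−hysteresis))`): in the high-force
   convergence zone states cannot be told apart, and the initial state of a
   half-cycle is assigned at the first resolvable sample. The floor also
   guarantees every accepted jump exceeds `min_jump`, so no per-event
   amplitude test is applied (a falsely rejected flip would desynchronize
   the alternation).

3. **Event coordinates.** The pre-jump force is read off the *fitted branch
   line* at the last pre-jump sample, not off the raw sample: the line
   pools hundreds of samples, which removes single-sample noise from every
   downstream force coordinate. This matters quantitatively — dwells in the
   hopping zone last only a few samples, and raw-sample endpoints would
   fake force spans of ±2σ where the true ramp progress is a few
   millipiconewtons, inflating the exposure at risk several-fold. The event
   extension is the horizontal distance between the fitted lines at that
   force, so the fraying regression is observable event by event.

4. **Dwells.** Each event list becomes survival records (state, entry
   force, exit force, censoring, ramp sign), with entry/exit read off the
   occupied branch line and intervals clipped to the resolvable force
   range — time spent where no transition could have been observed must not
   count as exposure.

**Dead time.** With 1 kHz sampling, a median-3 filter and two-sample
confirmation, dwells shorter than ~2 ms are invisible; both members of such
a hop pair are lost. For the tuned unmodified duplex this hides ~20% of all
events (they concentrate where the *arrival* state is unstable), which is a
property of the sampling rate, not of the detector settings. Consequences
and mitigations:

* Event recall among resolvable events (adjacent dwells ≥ 3 ms) is ≥ 98%
  at σ_F = 0.2–0.3 pN, with a false-discovery rate below 2%.
* The occurrence/exposure hazard is unbiased where the arrival state lives
  longer than the dead time, and biased low on the opposite flank. The
  Bell–Evans fits therefore use per-direction windows trimmed to 0.5 pN on
  the arrival-unstable side (B→S below the crossing, S→B above it) and
  1.2 pN on the stable side; both are configurable.
* `k(F_tr)` from the fitted-line crossing is biased low by the overall
  event loss (~15–20% for the defaults); the transition-state *distances*
  (slopes) are what the recovery tests pin down.

## Equilibrium estimators

* **`F_tr`**: S-state occupancy per 0.25 pN force bin (bin coordinate = mean
  force of its samples), fitted with the two-state logistic with free
  midpoint and width. With state-dependent branch forces the midpoint has a
  small intrinsic offset (≈ −K_trap·ΔX·(X_S→TS/ΔX − ½) ≈ −0.1 pN for the
  defaults); it is left uncorrected and is well inside the recovery
  tolerance.
* **Work per event** uses the pre-jump force. Because individual jumps
  happen over a ±1–2 pN band and lose ~1 nm of extension per pN (fraying),
  the raw per-event work mixes fraying states; each event's extension is
  therefore referred back to the transition force through the fitted
  fraying slope, `ΔX_i + m̂ (F_i − F̂_tr)`, before averaging. This targets
  `G_BS` *at the transition force* — the quantity the product `F_tr·ΔX`
  represents — and removes a ~2% underestimate. The uncorrected mean work
  remains available (`fray_slope=0`).
* **Bennett acceptance ratio** on the forward/reverse work samples (same
  fraying referral), solved by bracketing/bisection to 1e-6 kBT. On
  near-equilibrium data it lands within a fraction of a kBT of the mean
  work; the sign of the small difference is seed-dependent here, so no
  directional claim is asserted.
* **SEMs** by per-cycle bootstrap (200 resamples, seeded): events within a
  cycle share a tether and are correlated, so cycles are the exchangeable
  unit.
* `n = ΔX/x_BS` is reported unrounded; `g = G_BS/n`. The internal
  consistency `g ≈ F_tr·x_BS/k_BT` holds to ~0.1% on simulated data.

## Kinetics estimators

Survival curves are left-truncated Kaplan–Meier estimates per (state, ramp
phase), computed in the traversal coordinate (release phases run on the
negated force axis) — a dwell is at risk only between its entry and exit
forces, which is essential because most dwells start mid-window after a
previous jump. Force-resolved rates pool the event counts and force
exposure of both phases per bin, `k = r·d_j/(Y_j ΔF)`, which is the binned
product-limit hazard increment and coincides with `r·ρ(F)/S(F)` in the
continuum; the hazard-transform form is also provided and validated against
the analytic constant-hazard limit (`S(F) = e^{−k(F−F₀)/r}`, flat `k(F)`).

`g_TS` regresses `ln N` on `n` (ordinary least squares; the two-construct
case reduces to `ln(N_b/N_a)/(n_a−n_b)`), assuming the cycle duration is
fixed across constructs at a given protocol so that N is proportional to
the hopping rate near `F_tr`. The attempt rate undoes the extensive
barrier: `k⁰_BS = k(F_tr)·e^{n·g_TS}`. Zero-force rate extrapolations are
reported but are extrapolations only — the ramp never probes low force, and
the Bell–Evans slopes alone carry no barrier-height information.

## Free-energy profile

The per-bp profile at `F_tr` pins two equal minima (0 at the B extension,
0 at `x_BS = 0.23 nm/bp`) separated by a C¹ cubic-Hermite barrier of height
`g_TS` at the transition-state position (~0.14 nm/bp, ≈ 60% of the path);
beyond `x_BS` the quadratic S wall rises with per-bp stiffness
`3000 pN / 0.58 nm` (elastic modulus over rise; the B wall at negative
extension uses `1000 pN / 0.34 nm`). The interpolant between the anchored
points is illustrative; the quantitative content is the barrier height and
position and the endpoint values. Tilting to zero force adds `F_tr·x/k_BT`
pointwise; at `x_BS` this term equals the equilibrium per-bp free energy to
within 1%, and for all measured parameter sets the tilted profile rises
monotonically beyond the barrier — no metastable S minimum survives at zero
force (the metastability test demands an interior local minimum within 10%
of `x_BS` with an escape barrier above 0.05 kBT/bp). Grid resolution
0.001 nm/bp.

## Numerical choices and problem sizes

* Simulation substep 1e-4 s; sampling 1 kHz; 0.25 pN analysis bins; the
  two-state logistic fit needs ≥ 20 samples per bin; rate bins need ≥ 5
  events; Bell–Evans fits need ≥ 4 bins per direction.
* Recovery tests run 176 cycles of the unmodified preset (the published
  cycle count) at σ_F = 0.2 pN with a fixed seed; the module-level test
  fixture uses 40 cycles; the velocity-scaling comparison uses 100 cycles
  per velocity. A 176-cycle simulation plus full analysis takes a few
  seconds on one core.
* All randomness derives from a single root seed via spawned child streams
  (per construct, per stage), so dataset-level results are reproducible and
  independent of construct order.

## Known limitations

* Detected transition counts per cycle underestimate the true count by the
  dead-time fraction (~20% for the tuned unmodified duplex at 1 kHz); the
  barrier regression is unaffected to first order because the loss factor
  is similar across constructs at a fixed protocol.
* The crossing rate `k(F_tr)` inherits the same global loss factor.
* The logistic-midpoint `F_tr` carries the small branch-offset bias noted
  above.
* The profile interpolant between anchors is schematic by construction.
* The tether-loss / melting pathway is out of scope; low-salt behaviour is
  emulated only through parameter changes, not through a separate melting
  channel.
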