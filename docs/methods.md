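# Methods

## Model

The nucleus interior is described by a prescribed indicator field φ₀
(0 inside, 1 outside), chromosome territories by N phase-fields φ_m and
heterochromatin by one phase-field ψ, all on a rectangular domain
Ω = L_x × L_y discretized by a regular cell-centered grid. The chromatin
fields evolve by L² gradient flow of an energy with four groups of terms:

* **E0 — diffuse interfaces.** Gradient energy ε²/2 |∇u|² plus the double
  well g(u) = u²(1−u)²/4. The well is fixed so that −g′(u) = u(1−u)(u−½),
  which is the bistable reaction kernel appearing in the evolution
  equations; any other normalization of g would rescale the printed
  reaction terms. A flat equilibrium interface is the tanh profile
  u = ½[1 + tanh(x/(2√2 ε))], whose λ-band thickness
  δ = 4√2 ε artanh(1−2λ) is reported as the *intermingling width* (λ = 0.15
  throughout).
* **E1 — territory restrictions.** β₀ confines chromosomes to the nucleus,
  β_ψ confines heterochromatin to chromosome territories, β_φ penalizes
  territory overlap. The pair sum runs over *unordered* pairs; this is the
  convention under which the functional derivative reproduces the reaction
  coefficient 30 β_φ [χ − h(φ_m)] with χ = Σ_m h(φ_m).
* **E2 — volume constraints.** Full nuclear occupancy (α₀), chromosome
  volume targets (α_V) and heterochromatin volume targets (α_v), with
  volumes V_m = ∫h(φ_m), v_m = ∫h(φ_m)h(ψ) as midpoint Riemann sums. The
  occupancy term uses the instantaneous nuclear volume ∫[1−h(φ₀)],
  recomputed whenever the geometry schedule changes φ₀.
* **E3 — envelope affinity.** γ ∫∇h(φ₀)·∇h(ψ) models LBR / lamin A
  tethering of peripheral heterochromatin; γ = 0 models their absence.

Because the dynamics integrates the derived reaction terms A_m and B
directly, `total_energy` is diagnostic only — but with φ₀ and all targets
frozen the two agree, and the recorded energy is non-increasing along
trajectories (tested to a relative per-step tolerance of 10⁻⁶ at the
reference step size).

Two regimes differ only in the E2 targets. *Conventional*: constant V̄_m and
v̄_m. *Inverted*: V̄_m contracts to r·V̄_m and the heterochromatin target
tracks ρ_m(t)·V_m(t), where the conversion fraction ρ_m rises monotonically
from v_m(0)/V_m(0) by ρ̄_m, following either the sigmoid
ρ_m(0) + ρ̄_m t/(t + α₁e^{−α₂(t−t*)}) or the saturating form
ρ_m(0) + ρ̄_m t/(τ + t), τ = 10 (used by the phase-diagram scenarios).

There is no thermal noise: the model is deterministic, and all randomness
(initial sector offsets, per-chromosome heterochromatin fractions) flows
from a single scenario seed. Heterochromatin is one field — L1-rich
heterochromatin and chromocenters are not distinguished — and the model is
2-D, matching the image-analysis plane it is compared against.

## Non-dimensionalization

Length scale L = 5 µm (the 1.2 × 1.8 domain spans 6 × 9 µm around a
5 × 8 µm P0 ellipse) and time scale T = 5 h, giving mobility μ = 1/T =
0.2 h⁻¹. Dimensionless gradient coefficients map to µm² via ε²L²; με²L² is
the effective chromatin diffusion coefficient (0.9–3.7 ×10⁻³ µm²/h for
territories, 0.98–3.92 ×10⁻³ µm²/h for heterochromatin over the supported
ε² ranges — well below the ~0.16 µm²/h experimental mobility ceiling).

## Nucleus geometry

φ₀ is built from a signed-distance surrogate to the ellipse (the level-set
function r−1 rescaled by its local gradient; the error is far below the
interface width) through a tanh profile of squared width parameter ε₀. The
semi-axes interpolate linearly over a shrink window; "shrinks to f of its
size" means final *area* = f × initial area, because the volume constraint
R1 couples to area and the observed ~40 % decrease is a volume statement.
Equal-area circular or aspect-preserving elliptical end shapes are
supported. φ₀ never responds to the chromatin fields. `make_phi0` warns
when the λ-band of the interface spans fewer than 4 cells.

## Numerics

Plain forward Euler with a 5-point central-difference Laplacian and
zero-flux (mirror) boundaries; the boundary choice is immaterial because β₀
keeps all fields away from the box, but it is fixed for reproducibility.
A guard refuses configurations with max(ε_φ², ε_ψ²)(dt/dx² + dt/dy²) > ½.
φ₀, ρ_m(t) and the volume targets are refreshed at the start of every step
(first-order consistent). Fields are never clamped: the monitored
[−0.05, 1.05] band is logged on violation so parameter errors surface
instead of being masked. The inner loops are numba-jitted with an
arithmetically identical vectorized numpy path kept as the reference; the
test suite asserts both backends agree.

The reference discretization is dx = dy = 6×10⁻³ (200 × 300 cells) with
dt = 6×10⁻⁴. The `scaled_down` tier used by the regression tests runs
100 × 150 cells with dt = 2.4×10⁻³ (the same diffusive stability factor),
a wider nucleus interface (ε₀ = 10⁻⁴, keeping ≥ 4 cells across the
envelope band), and all schedule clocks (α₁, t*, τ, shrink windows,
horizons) divided by 8. The time compression is shape-preserving on ρ_m
(the compressed clock traces the identical curve against compressed time;
tested) and was chosen so that one reorganization run — ~68 000 steps,
about one to two minutes on one core — still traverses the same sequence
of architectures (peripheral heterochromatin → detachment → fusion →
single central cluster) as the published 9-month trajectories at reference
resolution (~2×10⁶ steps), which are reproducible through the same presets
with `--tier reference` but are multi-hour computations.

## Scenarios and initial conditions

`sector_init` builds the post-division state: the nucleus interior is
partitioned into N equal-area angular sectors ("pizza slices") with a
seeded random offset, smoothed by one equilibrium tanh width and normalized
so Σφ_m equals the interior indicator exactly (full occupancy at init is
within 5 %). Each chromosome's heterochromatin starts as a smoothed
peripheral cap spanning 70 % of its sector's angle with area fraction drawn
uniformly from [0.23, 0.28] (one seeded draw per chromosome, also used for
the conventional targets v̄_m = f_m V_m(0)) — distinct peripheral clusters,
as in newborn rod cells. Conventional targets use V̄_m = nuclear volume / N.

Reorganization scenarios start from the *conventional fixture*: the relaxed
state of the weak-territory conventional setup with positive envelope
affinity at t = 14.4 (the day-3 analogue, by which time the architecture is
insensitive to the territory-intensity choice). The fixture is regenerated
on demand and cached, never shipped as data. Its ρ_m(0) = v_m(0)/V_m(0) and
the P0 nuclear volume seed the inverted schedules. During the conventional
stage the peripheral caps spread along the tethering envelope and largely
merge — the day-3 heterochromatin is a near-continuous peripheral layer, so
the scaled reorganization trajectory shows the envelope-contact collapse
(0.51 → 0.09) rather than a long 8 → 2 → 1 fusion cascade.

Preset notes, where the published descriptions needed interpretation:

* The contraction ratio r defaults to the final/initial nuclear volume so
  the occupancy and chromosome-volume targets stay compatible during
  shrink (fig4: r = 0.6).
* The shrink window spans the first 10 % of the reorganization horizon:
  on the published chronology the nuclear size reduction completes about
  one month into the ~9-month process (by P28), after which the terminal
  cluster fusion proceeds in the small round nucleus. Ending the shrink
  with the run still leaves the envelope chasing the growing central
  cluster and no settling time.
* The unoccupied-nucleus ablation (fig5d) sets α₀ = 0 together with
  r = 0.49. With the occupancy term active the nucleus always refills
  (verified numerically: ΣV stays at ~0.99 of P0), so "unoccupied space"
  can only mean ablating R1 — and only then does total chromatin actually
  contract to ~49 % of P0 as described (measured 0.45 at the scaled tier).
* "80 % / 40 % cut-off" size reductions are exposed as explicit final-area
  fractions: 0.8 for the small-decrease arms (fig5b/c), 0.6 for fig5d.
* The conversion-clock symbols printed per chromosome group (120/150/80/250)
  are the t* of the sigmoid, with α₁ numerically equal and α₂ = 0.03.
* Two printed affinity strengths coexist (γ = 0.0022/3 for the conventional
  arms, γ = 0.022 for the affinity ablation); both are kept verbatim in
  their presets.
* The fig5a panel text and parameter listing disagree about whether the
  conversion schedule is active; the preset follows the panel's stated role
  (fixed nucleus, active conversion), which indeed yields the
  single-cluster inverted state.

## Readouts

* **Intermingling width**: closed form δ = 4√2 ε artanh(1−2λ); the measured
  λ-band width of a relaxed simulated interface (crossings located by
  linear interpolation) agrees within 10 % at reference resolution and
  within 3 % at double resolution.
* **Cluster count**: connected components of {ψ ≥ 0.5}, 4-neighborhood.
  Threshold and connectivity are explicit configuration — the published
  description has no operational definition — and 8-connectivity changes
  none of the packaged examples' counts.
* **Contact fraction**: mean of h(ψ) over the envelope-adjacent shell (the
  φ₀ interface annulus dilated inward by one heterochromatin interface
  width), weighted by the nucleoplasm indicator 1−h(φ₀) so the exterior
  tail of the diffuse envelope does not dilute it.
* **Classification**: *inverted* when contact < 0.1 (single vs multi by
  cluster count); *conventional* when contact ≥ ½ × the mean
  heterochromatin share of the nucleoplasm; otherwise *intermediate*.
  Invariant under rotations and mirrors (tested).
* **Phase boundary**: per nuclear size, the minimal δ_ψ (maximal δ_φ) whose
  sweep run ends single-cluster inverted; non-monotone sweeps are flagged
  and reported raw.

## Limitations

* The qualitative regressions run at the scaled tier; reference-resolution
  9-month trajectories and the full intermingling phase diagrams (δ_ψ and
  δ_φ sweeps at several nuclear sizes) are supported through
  `nucarch run/sweep --tier reference` but are hours-long computations and
  are not part of the test suite.
* The quoted "minimal interface width / grid size ≈ 26.33" of the original
  numerical setup cannot be reproduced from δ = 4√2 ε artanh(1−2λ) with
  λ = 0.15 and the supported ε ranges (which give ≈ 11); whatever width
  convention produced it, it is not used as a check here.
* The synthetic initial conditions idealize the post-division nucleus:
  equal-area sector territories, no nucleoli, chromocenters merged into the
  single heterochromatin field, and deterministic dynamics. Passing
  regressions therefore demonstrate the model's mechanism — not image-level
  agreement with FISH data.
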