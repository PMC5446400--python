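# Methods

This note records the models behind each module, the parameter choices
that matter, and what the synthetic benchmarks do and do not demonstrate.

## Device geometry and design arithmetic

A DLD stage is specified by its pillar footprint, lateral gap `g`, lateral
pitch `λ`, row shift `s`, shift fraction `ε`, reset/column counts and
ceiling height `h`. Invariants enforced at construction: `λ` equals the
pillar's lateral extent plus `g`, and `s` equals `λ·ε` to within the 1 µm
the chip layout rounds to. The built-in two-stage device is: Stage 1 —
50 µm cylinders, `g = 63`, `λ = 113`, `s = 16`, `ε = 1/7`, 8 columns,
12 resets, `h = 90`; Stage 2 — 77 µm (lateral) × 60 µm (along-flow) hybrid
pillars, `g = 63`, `λ = 140`, `s = 20`, `ε = 1/7`, 32 columns, 48 resets,
`h = 30`. Both stages deflect 1/3 of their flow to product.

Critical diameter estimators: plug `D_c = 2gε`; parabolic `D_c = 2gx`
with `3x² − 2x³ = ε` solved by Brent's method to `|f| < 1e−10` (the
flux-weighted width of the wall lane under a parabolic cross-gap
profile); Davis `D_c = 1.4·g·ε^0.48`. The parabolic method is the
default: it reproduces the 30 µm design value at the chip's `g`, `ε`,
while the Davis correlation gives 34.7 µm. Both are reported by the
design CLI so the discrepancy stays visible.

Two readings the documented layout leaves open, resolved as follows. The
hybrid footprint "77 × 60" is taken as 77 µm lateral × 60 µm along-flow,
because only 77 + 63 = 140 µm of lateral pitch reproduces the documented
20 µm = λ/7 row shift. The stored `rows_per_reset = 10` is kept as layout
metadata only; all trajectory and reset logic uses `1/ε = 7` rows per
reset (the value at which the cumulative shift equals one pitch), and the
minimum reset count for full-width displacement is the column count
(32 columns → 32 resets minimum, +16 safety margin → 48).

The exact "I"-groove dimensions of the Stage 2 pillar are nowhere fixed;
they are exposed as fractions (groove width 1/3 of the rectangular half,
groove depth 1/4 of the lateral extent, elliptic half 1/2 of the
along-flow extent) and the rasterizer checks its footprint area against
the analytic shape to 2%.

## Hydraulics

Rectangular-duct resistance uses the first-order aspect-ratio formula
`R = 12µL/(w a³(1 − 0.63 a/w))` with `a` the short dimension. Note the
correction factor makes "halving `a` multiplies R by 8" only approximate
(the true factor is slightly below 8 at any finite aspect). The flow
network solver is a standard nodal-conductance linear solve; outlet
splits are designed by resistance ratio (`R_other = R_fixed(1−t)/t` for
the branch carrying fraction `t`), and a helper solves the one free
dimension of a compensation channel (e.g. the 340 mm long, 200 µm high
channel on the Stage 1 product path) by root finding. Viscosity defaults
to 1 mPa·s everywhere — the same uniform-Newtonian assumption the
device's own shear analysis rests on; blood shear-thinning is out of
scope. TYGON tubing appendages can be added as Poiseuille resistances but
are off by default.

The analytic peak-shear screen takes the mean gap velocity
`U = Q_gap/(g·h)`, a 1.5× midplane amplification, and the larger of the
depth-wall (`6µU_mid/h`) and cross-gap (`6µU_mid/g`) parallel-plate
estimates. It is an order-of-magnitude screen; the unit-cell solve below
is the quantitative path.

## Unit-cell flow solver

The array is periodic up to the row shift, so one pillar in a
`λ × λ` box with *shifted-periodic* boundaries (`field(x+λ, y) =
field(x, y−s)`) represents the whole stage. The solver models the
depth-averaged in-plane velocity with the Stokes–Brinkman equation
(`−∇p + µ∇²u − (12µ/h²)u = 0`), the exact depth correction for a locally
parabolic profile across a slab of depth `h`. In streamfunction form the
pressure vanishes and the problem is a single biharmonic-type solve,
`µ∇⁴ψ = ∇·(α∇ψ)`, with `α = 12µ/h²` in the fluid and a volume
penalization value inside the pillar mask (`α_s = 12µ/η²`, `η = 0.25 µm`,
penetration depth ≈ 0.07 µm, far below the grid). Discretization is a
13-point compact stencil on a uniform grid (default 1 µm/cell) with the
shift built into the x-wrap index maps; the system is solved directly
(sparse LU). Because the streamfunction jump across one lateral pitch
*is* the imposed flux and the problem is linear, the target per-gap flow
is achieved exactly rather than iteratively, and the discrete divergence
vanishes to round-off by operator commutation (both are asserted in
tests).

Consequences checked by the suite: no-slip holds to <1% of the mean
velocity on the pillar boundary; fields scale exactly with flux (Stokes
linearity); an empty cell recovers uniform plane flow; and halving the
grid from 1.0 to 0.5 µm moves the Stage 1 peak shear by ~1% and the
streamline critical diameter by ~0.4%. (The convergence check uses
1.0 → 0.5 µm because the 113 µm Stage 1 pitch is not divisible by 2 µm.)

**Wall shear.** Midplane values are 1.5× depth-averaged. Pillar-wall
shear is extracted per column from a one-sided second-order fit anchored
at the analytic wall position (u = 0 at the wall, speeds sampled at one
and two grid spacings along the lateral normal); floor/ceiling shear is
`6µ|u|/h`. The global peak at the 0.5 mL/hr budgets is 3.04 Pa in
Stage 1 (pillar wall at the gap throat) and 5.57 Pa in Stage 2
(floor/ceiling-dominated, shallow cell) — the sharp flange corners of
the hybrid pillar carry a corner singularity whose local values are
mesh-sensitive, which is why the coarse-grid hybrid solve is not used
for convergence claims.

**Streamline critical diameter.** The first-stream width β is measured at
the gap throat (minimum clearance) from the streamfunction profile: β is
the station where `(ψ − ψ_wall) mod Q` reaches `ε·Q` (modular arithmetic
makes the measurement agnostic to any branch cut a synthetic field
carries), and `D_c = 2β`. With the shifted-periodic cell every row is
equivalent, so one throat profile is the row average. On the Stage 1
cylinder cell this gives 27.7 µm vs the 29.97 µm parabolic analytic value
(the Brinkman depth drag flattens the profile slightly).

**Streamline-asymmetry score.** The relative L2 difference between the
speed field and its mirror about the cross-gap line through the pillar
center (upstream ↔ downstream). Stokes reversibility makes any fore-aft
symmetric pillar in an *untilted* array score ≈ 0 (the cylinder measures
~1e−12, and < 0.05 is used as the discretization threshold); the row
shift alone contributes ~0.10 for either shape; the grooved/elliptic
hybrid scores 0.23 on its operating cell versus 0.10 for the cylinder.
The lateral (cross-stream) mirror is *not* used because both footprints
are laterally symmetric — it cannot rank the shapes.

A synthetic plug-profile field (uniform speed across every gap, built
from a piecewise-linear streamfunction with a single global wall value)
serves as the closed-form oracle for transport: its first-stream width is
exactly `g·ε`. Its one construction artifact is that the gap transition
collapses into a single column, which biases bump-exit streamlines by a
couple of micrometres near the pillar nose; dichotomy tests therefore use
sphere sizes 20–45% away from the threshold.

## Transport model

A reduced kinematic model, standard for DLD reasoning: the particle
centroid follows the local depth-averaged velocity (RK2 steps of one grid
cell), and a hard-contact rule keeps the centroid at least one effective
radius from pillar surfaces, using a smoothed, interpolated Euclidean
distance transform of the shifted-periodic tiling (raw nearest-node
normals are noisy enough at the pillar nose to push particles across the
first-stream separatrix). While resting on a pillar only the tangential
velocity advances the particle; on the stagnation line the slide
direction is chosen by the particle's own streamfunction value relative
to the wall streamline. No hydrodynamic resistance tensors, lift,
deformation or particle–particle interactions are modeled — absolute
blood-run efficiencies are out of scope; the model reproduces mode logic.

Mode classification follows the per-reset drift: displaced when the mean
lateral displacement per reset is ≥ 0.9·pitch, zigzag when ≤ 0.1·pitch in
magnitude, mixed between. The first reset interval is an entry transient
(the particle is still migrating to its steady orbit) and is excluded
from the drift mean. On the solved Stage 1 field the sphere mode flips
between 26 and 28 µm, consistent with the 27.7 µm streamline `D_c`, and
is deterministic across seeds.

**Cluster orientation.** Clusters are rigid sphere assemblies (random
sequential attachment in the generator; connectivity of the contact
graph is a constructor invariant). Principal extents include member
radii. Under the tall Stage 1 ceiling the long axis is near-vertical:
tilt is drawn from a folded normal with σ = 10° (so ~90% of 2:1 clusters
present within ~11% of their transverse axis); the stated tendency is a
distributional choice, not a measured quantity. Under the 30 µm Stage 2
ceiling the cluster lies flat with a uniform random initial in-plane
angle, and a cluster whose flattest pose exceeds the ceiling is flagged
jammed and excluded from flow.

**In-plane rotation.** Jeffery-orbit dynamics: spin at half the local
vorticity plus the strain coupling `B(−E₁₁ sin 2φ + E₁₂ cos 2φ)`. The
shape factor defaults to the rod/aligning limit `B = 1`, so an
undisturbed elongated cluster settles toward flow alignment and presents
its transverse axis — the behavior the grooves must beat. Wall contact
blocks extent-increasing rotation (the reaction torque) while leaving
alignment free. The groove-alignment impulse applies in the upstream
(grooved) half of the pillar footprint during free flight:
`ω += k·γ̇·sin 2φ` toward the cross-flow pose, with gain `k = 5`
(dimensionless). The gain is the model's one explicitly free parameter —
no documented quantity fixes it — and is calibrated once so that 2-cell
clusters of 14 µm cells (transverse axis well under `D_c`) deflect with
grooves and mostly zigzag without, mirroring the reported
asymmetric-vs-cylindrical pillar contrast qualitatively. The experimentally measured
capture percentages from that comparison are biological outcomes and are
not targets of this model.

`simulate_device` routes Stage 1 displaced particles to Stage 1 product,
re-orients the rest under the Stage 2 ceiling, and splits the remainder
into Stage 2 product and waste. Size classes: single (1 cell), small
cluster (2–8), large cluster (≥ 9) — the member-count mapping implied by
the 3169 µm² / ~8.67-cell area cutoff. Device simulations default to a
few resets per stage (not the physical 12/48) to keep runs interactive;
the steady orbit is reached within one reset, so mode calls are
unaffected.

## Enumeration pipeline

Background is estimated by coarse median filtering (downsample 16×,
median over 15 coarse pixels, upsample): adaptive to slow shading while
ignoring objects much smaller than the window, in the spirit of
adaptive-background thresholding. Foreground is background + offset
(default 25 intensity units); objects under 60 µm² are discarded.
Touching cells are split by watershed on the smoothed distance transform
with seed separation ≈ one cell diameter (14 µm). Neighbors are cells
whose regions touch within a 1-pixel dilation; events are connected
components of the neighbor graph. Classification is exactly: isolated
cell → single; component area strictly greater than 3169 µm² → large
cluster; otherwise small cluster. The default pixel scale 0.65 µm/px is
derived from the canonical cutoff pair 3169 µm² ↔ ~7500 px
(√(3169/7500) ≈ 0.65); the config asserts the pair's consistency.
Overlay colors: single blue, small yellow, large red.

Fixed-offset thresholding on a blurred edge measures areas a few percent
high of the geometric disc (the threshold sits below the half-maximum
for bright cells); this matters only within a few percent of the area
cutoff, and the benchmark accuracy accounts for any resulting class
flips.

## Synthetic data

Cluster-size distribution: log-series with p = 0.8 truncated at 120
cells — heavily weighted to 2–4-cell aggregates with a tail past 100,
matching the qualitative regime the device targets (the true culture
distribution is not documented; this default is a labeled stand-in).
Single-CTC diameters uniform 4–30 µm; RBC-like 8 µm and WBC-like 12 µm
fixed. Cluster member cells 15 ± 1.5 µm diameter for transport, and
disc radius 10.8 ± 0.8 µm for rendering (area ≈ 366 µm², the single-cell
reference the cutoff's "~8.67 cells" implies).

Frames are 1392 × 1040 px at 0.65 µm/px (a typical 10× camera format),
~18 events/frame (Poisson), class mix 50% singles / 40% small (2–8
cells) / 10% large (9–15 cells), flat discs with per-cell brightness
110–200 over background 40, PSF blur σ = 1.2 px, Gaussian noise σ = 6.
Ground truth records each event's class, union-of-discs pixel area,
member count and a clipped flag (border events are excluded from
accuracy scoring). What passing the ≥90% benchmark shows: the
segmentation–grouping–classification logic is correct and robust to
PSF blur, brightness variation and read noise. What it does not show:
performance on real blood-run imagery with RBC clutter, debris, uneven
illumination or focus drift — agreement with manual counting on real
frames is the analogous check, not reproduced here.

Benchmark accuracy is pooled over 50 frames: a ground-truth event counts
when exactly one detected event claims the majority of its pixels and
carries the same class (greedy one-to-one overlap matching). Measured:
~96–97% across seeds.

## Statistics

Partition fractions are per-replicate normalized percentages with sample
SD across replicates; recovery is the product-stream sum (identically
100 − waste). When only summary per-stream fractions are available the
recovery SD is combined in quadrature, which ignores the anticorrelation
through the shared denominator — with replicate tables the per-replicate
recovery SD is computed directly, and both paths are exposed. Log₁₀
depletion is `log10(input/output)` with counts = concentration × volume;
zero output is reported as a censored bound ("> log10(input)"), the
counting-chamber detection floor, never infinity. Viability comparisons
use a pooled-variance two-sample t test on replicate percentages
(two-sided, α = 0.05, matching CI): with duplicate experiments the
pooled test has df = 2 and flags the high-flow-rate conditions while
Welch's df ≈ 1.4 does not separate them; the source experiments name no
test, so the pooled choice is this package's. The ≥200-cells-per-
condition rule is enforced at record construction. Cytometry gating:
nuclear⁺ required; epithelial⁺/leukocyte⁻ → cancer; viable iff
viability⁺ and apoptosis⁻ — every event falls in exactly one of four
bins.

## Known limitations

- The 2D Brinkman model under-resolves 3D corner flows; hybrid-pillar
  corner shear is mesh-sensitive and the reported peak deliberately
  comes from smooth wall segments at the operating resolution.
- The kinematic transport model has no hydrodynamic interactions, so
  absolute capture efficiencies (especially in blood, where cell
  crowding inhibits rotation) are outside its reach; ablation and
  monotonicity statements are qualitative model properties.
- The groove impulse gain is a calibrated free parameter, not a derived
  quantity.
- Synthetic frames omit blood background; enumeration accuracy on them
  is an upper bound on real-image performance.
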