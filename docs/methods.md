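# Methods

This note documents the models, the statistics, the parameter choices that
were genuinely open, and what the synthetic-data generators do and do not
emulate.

## 1D circular-track model

Cells occupy integer sites on a ring of `L` sites and all move in the same
direction, one site per step; directional reversals are deliberately absent.
A site may hold any number of agents ("side by side" in the unmodeled
transverse direction). A cell attempting to enter a site holding `n` spores
succeeds with probability `P^n` (`P^0 = 1`): spores impede passage, and
multiple spores compound multiplicatively.

C-signal dynamics: each cell starts with a concentration drawn uniformly
from `[0, 0.5)` and gains `0.005` per step (basal production) plus
`T · c̄`, where `c̄` is the mean concentration of the *motile* cells one site
ahead and behind. Spores are excluded from the average because signaling
requires movement; cells sharing the agent's own site contribute nothing; if
both neighbor sites are empty of motile cells the transfer term is zero.
Concentration never decreases. A cell reaching concentration `≥ 1.0`
converts, after the signaling update of the same step, into a spore at its
current site. Basal production alone guarantees termination within
`ceil(1.0 / 0.005) = 200` steps.

**Phase order.** Each step: movement, then signaling (synchronous, computed
from pre-update concentrations), then conversion. Within the movement phase
the spore occupancy is frozen (conversions happen at the end of the step),
so per-agent move outcomes are mutually independent; the implementation
therefore updates all agents at once, which is distributionally identical to
any sequential order and makes 10,000-run parameter sweeps cheap
(`run_track_batch` additionally vectorizes across replicates).

**Track density.** The ring length and cell count are free choices; the
observable amplitudes depend on them. The defaults `L = 100`, `N = 100`
(one cell per site) were calibrated once against the two published
amplitudes of the sweep: a ~50% relative increase in mean void fraction
between free flow (`P = 1`) and strong jamming (`P ≈ 0.05–0.1`) at `T = 0`,
and per-site spore clusters reaching 5–10 at the lowest passing
probabilities. At this density the free-flow void fraction is
`(1 − 1/L)^N ≈ 0.366`. Sparser tracks (e.g. 0.6 cells/site) reproduce the
qualitative sweep shape but compress the jamming amplitude to ~17%.

**Seeding.** A single generator per run; sweeps derive one independent
`SeedSequence` per (P, T) pair from the base seed and pair index, and run
all replicates of a pair from that stream.

## 2D flexible-rod swarm model

Cells are three-node chains (two segments of rest length `l₀ = 2.5 µm`,
body width 0.5 µm) on a periodic square domain. The elastic energy is the
standard harmonic form

```
H = ½ k_b θ² + ½ k_s Σᵢ (lᵢ − l₀)²
```

with `θ` the deviation-from-straight angle between the segments. Defaults
`k_b = 5` energy/rad², `k_s = 10` energy/µm² at Metropolis temperature 1
give a persistence of shape (thermal bend sd ≈ 0.45 rad) floppy enough to
resolve collisions by bending but stiff enough to keep segments within 20%
of rest length on time average; both are config-exposed, as are the
direction weights below, since no authoritative values are available.

**Movement.** Per step (duration `dt = 0.1` min, shuffled agent order):

1. *Reversal:* when the cell's clock elapses, head and tail identities swap
   (coordinates untouched); the next reversal is scheduled one
   truncated-normal `N(8, 1)` min interval *after the previous due time*, so
   interval statistics are unbiased by the step quantization. Reversals are
   independent of C-signal.
2. *Direction:* `d = normalize(w_A â + w_S ŝ + w_T t̂ + w_n η̂)` with
   `â` the head-ward long axis, `ŝ` the mean orientation (sign-rectified
   toward `â`) of motile cells whose bodies come within half a cell length
   of the forward corridor one cell length ahead of the head, `t̂` the
   slime direction at the head (sign-rectified), and `η̂` a uniform random
   unit vector. Defaults `w_A = 1.0, w_S = 0.5, w_T = 0.5, w_n = 0.1` keep
   A-motility dominant with all factors active. A zero resultant falls back
   to `â`.
3. *Head displacement* by `v·dt` (speed 2 µm/min — typical gliding speed).
4. *Metropolis relaxation* of middle and tail. The first proposal rigidly
   translates the trailing nodes by the head displacement — for a body at
   rest shape this has exactly zero energy change, so an unobstructed cell
   moving straight never stalls; the remaining proposals (budget 10 total)
   draw Gaussian displacements (sd `0.1·l₀`) about the pre-move positions.
   A candidate is rejected as a collision if it creates or deepens a body
   overlap (capsule–capsule between cells, capsule–disc against spores;
   surfaces may touch but not interpenetrate further than they already do,
   which lets initially overlapping cells disentangle); otherwise it is
   accepted with probability `min(1, exp(−ΔH/T))`. If no candidate is
   accepted the head displacement is reverted and the cell stalls for the
   step.
5. *Slime deposit:* the cell writes its orientation with unit weight into
   the 1 µm slime grid under five sample points along its body; deposits
   are accumulated nematically (sign-aligned with the stored vector) and
   the whole field decays exponentially with a 10 min half-life. `t̂` is
   the weight-averaged direction within 1 µm of the head.

**Signaling.** Once per step, all motile pairs are tested: a pair signals
when (i) some end node of one lies within the contact distance of an end
node of the other, (ii) the acute angle between body axes is < 30°
(polarity ignored), and (iii) the midpoints are farther apart than one
segment length — this last condition excludes side-by-side lateral contact.
Both members gain +1 per qualifying pair; a cell in k pairs gains k. At 500
events a cell converts: its body collapses to a disc of radius 1 µm at the
former midpoint, it stops moving and signaling, but remains a collision
obstacle.

*Contact distance.* Collision resolution keeps body surfaces at least one
cell width (0.5 µm) apart, so resting end-to-end tips sit at ≈ 0.5–0.6 µm;
a threshold equal to the width would therefore never fire. The default
contact distance is 1.0 µm — the collision floor plus one half-width of
slack — so that geometrically "touching" end pairs qualify.

**Initial conditions.** Cells are placed uniformly (optionally restricted
to the discs for scaled runs), straight and at rest length. A cell whose
midpoint falls inside a disc is oriented tangent to the disc radius with
its head pointing counter-clockwise, seeding a consistent rotation (a
random head sense would cancel the net circulation the tangency is meant to
set up); other cells get uniform random orientations. Reversal clocks are
drawn from the interval distribution. Note the near-synchronized first
reversal this implies: a collective polarity flip inverts the signed
angular momentum without destroying the circulation, which is why the
rotation-sense test observes a window shorter than one reversal period.

**Neighbor queries** use a uniform spatial hash with cell-length bins and a
±2-bin search, exact for all interaction radii used.

**Scaled study conditions.** The full four-disc, 500 µm configuration is
the default. Quantitative tests use a scaled single-disc condition — a
140 µm periodic domain containing one 50 µm disc with 300 cells placed
inside the disc — and stop either at a spore-count target (100 spores ≈ one
third of the population) or a step cap. These sizes keep a full sporulation
study to a few thousand steps while preserving the in-disc density regime
of the full setup.

## Volumetric image statistics

Conventions: `x` = column, `y` = row of `I[y, x]`; orientation in degrees,
counter-clockwise from +x in the index frame, reported on (−90, 90].

- *Moments:* `m_pq = Σ_x Σ_y x^p y^q I(x, y)`, intensity-weighted (never
  binarized); central moments about the intensity centroid.
- *Equivalent ellipse:* covariance from normalized central moments
  (`μ'₂₀ = μ₂₀/μ₀₀` etc.); semi-axes `2√λ` from the eigenvalues — exact for
  a uniformly filled ellipse, whose variance along a semi-axis `a` is
  `a²/4`. Near-isotropic fits (eccentricity < 0.05) are flagged since their
  orientation is unconstrained.
- *Grayscale:* ITU-R 601 luminance weights (0.299, 0.587, 0.114).
- *Radial profiles:* pixels binned by the affine-invariant normalized
  elliptical radius of the fit; 20 equal-width annuli by default.
- *Angular profiles:* pie-slice sectors counter-clockwise from +x; the
  sector width (default 10°) must divide 360; the analyzed mask defaults to
  pixels ≥ the outer-shell isovalue 10.
- *Histograms:* per-plane 256-bin counts over the mask, an area-normalized
  copy, and a 5-bin centered moving average whose edge overhang is folded
  back so total mass is conserved exactly.
- *Axes vs height:* per-plane fits restricted to pixels ≥ the isovalue;
  ordinary least squares of each semi-axis (µm) against height (µm). A
  cone-like mound gives negative slopes with R² near 1.
- *Pockets:* 26-connected components of the ≥-isovalue voxel mask; volume,
  equivalent spherical diameter and centroid per component; a minimum voxel
  count (default 1, tests use 5) suppresses single-voxel noise hits.

## Point-pattern statistics

The analysis window is a square centered on the disc (side 2 × 1.2 × the
disc radius by default, i.e. 120 µm for a 50 µm disc) divided into a
100 × 100 grid, mirroring the 400 × 400-pixel window of the reference
analysis. Spore counts per cell form the concentration grid; the local
density field convolves it with a unit-mass Gaussian (default σ = 2 grid
cells ≈ one OCT lateral resolution element), with edge truncation
renormalized by the smoothed window indicator, so interior mass is
conserved exactly. Radial curves average the field over one-grid-cell-wide
rings. Angular counts use 3° sectors (120 per turn) computed from the raw
in-disc points by default — exact, and agreeing with the grid-cell variant
(also implemented) in the limit.

## Synthetic-data generators

All generators are deterministic under their seed and return ground truth.

- *Ellipse phantoms:* uniform-intensity ellipses with 4 × 4 subpixel
  coverage sampling, so boundary pixels carry fractional intensity and
  image moments match the continuous ellipse to well under the 2% test
  tolerance even at semi-axes of 5 px.
- *Mound volumes:* a linearly tapering elliptical cone (default base
  semi-axes 60 × 40 µm, apex 90 µm) with interior intensity 130 (middle of
  the observed 120–140 band) plus additive Gaussian noise (sd 8, clipped to
  8-bit), background 2 (below the shell isovalue 10), and spherical pockets
  of 12–25 µm diameter adding +40. Pocket centers are rejection-sampled
  with surfaces kept ≥ 2 voxels apart — separation by merely one pocket
  diameter lets unequal pockets touch and merge under 26-connectivity.
- *Clustered spore patterns:* Poisson-sized isotropic Gaussian clusters
  around uniform in-disc centers.

What these do **not** emulate: OCT speckle and attenuation physics,
refractive-index distortion, anisotropic voxels, irregular mound surfaces,
and spore-size exclusion effects in point patterns. Recovery tests on them
validate the estimators' contracts, not instrument realism.

## Known limitations

- Supplementary parameter values for the 2D model (direction weights,
  elastic coefficients) are not publicly available; the defaults here are
  reasoned stand-ins and all quantitative claims tested against them are
  restricted to properties insensitive to their exact values (reversal
  statistics, threshold accounting, geometric gates, clustering vs null).
- The 1D model's absolute void fractions are density-dependent; only the
  calibrated default density is tested quantitatively.
- The 2D model is two-dimensional: it addresses in-plane cross-section
  patterning, not 3D mound mechanics, nutrient dynamics or cell lysis.
- Signed circulation in a disc alternates with the near-synchronized early
  reversals; long-horizon rotation statistics are therefore not asserted.
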