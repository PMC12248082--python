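# Methods

This note documents the models behind the synthetic-data generators, the
measurement conventions, the numerical choices, and what the test suite
does and does not establish about real data.

## Synthetic arbors

Starburst amacrine cells are planar, radially symmetric neurons. The
generator grows `n_primary` *trunks* from a soma node at the origin, each
a biased random walk in the xy plane: at every step of length `step_len`
the direction is the normalized blend `b·r̂ + (1−b)·η` of the outward
radial unit vector and an isotropic unit noise vector, with
`radial_bias = b ∈ [0, 1]`. Each node receives independent Gaussian z
jitter (`z_jitter_sd`, default 0.3 μm) to emulate a near-planar arbor in
a confocal stack. Trunks stop when they reach `target_radius` (the final
node is clipped onto that radius, so no tip exceeds 1.1× the target).

While a trunk grows it spawns **side branches** as a Bernoulli process
with probability `branch_rate × step_len` per step. Side branches grow
outward with the same walk for a length drawn uniformly in 10–30% of the
target radius (or until the radius cap) and do not branch further. This
single-generation scheme is a deliberate design choice: the expected
branch-point count is `branch_rate × total trunk length`, *linear* in the
rate, so doubling `branch_rate` doubles branching density while leaving
the dendritic field area — set by the trunks — essentially unchanged.
That is exactly the phenotype contrast the analyses are designed to
detect (branch density roughly doubles with no change in field size). A
fully recursive bifurcation process cannot express that contrast: its
branch count grows like `exp(branch_rate × radius)`, coupling branch
density and arbor structure exponentially.

Dendrite diameters taper linearly from the proximal to the distal value
of `caliber_taper` (defaults 0.8 → 0.3 μm) over the radius. With
`hypertrophic=True`, exactly one randomly chosen trunk instead carries a
proximal-half diameter drawn uniformly in 1.2–2.0 μm (tapering to the
distal value beyond); only the >1 μm threshold is principled, the range
is a modelling choice. The soma is a single node of radius 4.5 μm,
typical for this cell type.

Genotype presets (`control`, `pten_cko`) are *qualitative*: branch rate
0.32 vs 0.64 per μm of trunk (≈ 200 vs ≈ 400 branch points at the 150 μm
default radius), hypertrophic probability 0 vs 0.8. They mirror the
direction of the biological effects, not their exact magnitudes; in
particular total dendritic length grows with branch rate here, whereas
the biological knockout roughly preserves it.

## Synthetic mosaics

`dmin = 0` gives a binomial (CSR) pattern. Hard-core patterns use random
sequential addition with a bucket-grid conflict check and up to five
restarts. Beyond the RSA jamming density (~0.55 disc coverage) dart
throwing cannot finish; the generator then falls back to a jittered
hexagonal lattice whose spacing still respects `dmin`, and raises a
`GenerationError` naming `dmin` and `n_points` only when even the
lattice cannot fit. Lattice-backed mosaics are nearly crystalline — far
more regular than biological mosaics — and are intended for stress
testing the spacing statistics, not as realistic tissue.

## Synthetic MEA responses and layout

Spike counts are per-epoch Poisson draws. Direction-selective units fire
at `baseline + amplitude·exp(κ(cos(θ−μ)−1))` spikes/s with μ drawn
uniformly from the direction set (default 12 directions at 30°, 3 s
epochs); non-selective units fire at baseline everywhere. The simulator
emits counts, not spike times, because every downstream statistic is
count-based. Ground-truth labels travel with the data so classifier
recovery can be scored.

The layout builder produces a square grid with the given pitch; the row
count is the largest k with `(k−1)·pitch + electrode_side` within the
span, allowing an overhang of up to 5% of the pitch because quoted array
spans are nominal (a 64 × 64 grid at 60 μm pitch with 21 μm electrodes
spans 3801 μm, quoted as 3.8 mm; 4096 sites).

## Lamination and puncta generators

Lamination profiles are sums of Gaussian bands in normalized IPL depth
(defaults 0.3 and 0.7 — placeholders for the two SAC strata, whose true
depths are parameterized, not asserted) plus zero-truncated Gaussian
noise. Depth 0 is the INL/IPL border by convention; flip upstream if
acquired the other way.

Puncta are placed uniformly over dendritic length, rejecting positions
below `inner_boundary` in normalized soma distance (default 2/3,
emulating output sites confined to the outer third of the arbor).
Diameters are truncated-normal above zero; volume is the equivalent
sphere `(π/6)d³`.

## Measurement conventions

* **Sholl**: spheres in 3-D centred on the soma centroid, radii at fixed
  steps up to the radial extent (max node distance from the soma
  centre). A segment crosses radius r when exactly one endpoint lies at
  distance < r; an endpoint exactly at r counts as outside, which
  prevents double counting. The 10-bin normalization averages counts over
  each successive 10% of the radial extent, making cells of different
  sizes comparable.
* **Self-crossings**: unordered pairs of node-disjoint dendrite segments
  whose xy projections properly intersect (strict interior crossing) and
  whose interpolated z values at the crossing differ by ≤ `z_tol`
  (default 0.5 μm, emulating visibility within one confocal z-plane; the
  stack spacing of any given dataset should set this flag). Segments
  sharing a node are branching, not crossing. A KD-tree on segment
  midpoints prunes candidate pairs; results equal the all-pairs oracle.
* **Hypertrophy**: max dendrite diameter over nodes farther than 5 μm
  from the soma centre (so the somatic taper cannot trigger the rule),
  called hypertrophic strictly above 1.0 μm.
* **Puncta filter**: "smaller than 0.5 μm" is read as volume-equivalent
  diameter with strict exclusion below the cutoff (a punctum at exactly
  0.5 μm is retained); the threshold and reading are flag-overridable.
  Soma distances are straight-line Euclidean, not path length along the
  dendrite.
* **Regularity index ratio**: the closed-source tool used for the
  original analyses does not publish its formula; here the observed NN
  regularity index is divided by the median index of matched CSR
  simulations (same n and window) — a reproducible reading of
  "compared to a random distribution". It is ≈ 1 for random patterns and
  > 1 for mosaics.
* **DRP**: reference points are restricted to an interior guard zone of
  width `max_radius` (border method), so annuli never leave the window.
  The effective radius converts the central deficit into the radius of
  the equivalent ideal hard-core step. The deficit is measured against
  the *recovered* density — the area-weighted plateau of the outer half
  of the profile — rather than the global n/area: all annuli share the
  realized density of the reference region, whose ~1/√n_ref fluctuation
  around the global mean would otherwise masquerade as an exclusion
  radius (≈ 15 μm at n = 2000 for a one-SE-sparse region). Both
  densities are reported.
* **DSGC thresholds**: strict `>` for DSI 0.37 and fit quality 0.5
  ("greater than"), inclusive `≥` for the 400-total-spike and 10
  average-preferred-spike floors ("minimum of"). Goodness of fit is
  operationalized as R² between observed and fitted tuning curves; the
  fit uses per-direction mean counts with one deterministic optimizer
  start per observed direction (analytic Jacobian, bounded
  baseline/amplitude/κ ≥ 0), so results are independent of unit order
  and run-to-run identical. Flat tuning curves are defined to have
  R² = 0 and κ = 0 rather than raising. Preferred direction is the
  argmax of mean counts with ties broken toward the smaller angle; the
  null direction is its exact opposite (the direction count is even by
  contract).
* **FWHM**: closed form `2·arccos(1 − ln2/κ)` in degrees; below
  κ = ln2/2 the curve never falls to half amplitude and the width is
  reported as 360°.
* **Fisher exact**: two-sided by the sum-of-small-probabilities
  convention (the convention that reproduces the published 0.0003 for
  13/16 vs 1/12), computed with log-factorial arithmetic and a 1e-7
  relative tie tolerance; any zero margin gives p = 1. Mid-p and
  tail-doubling conventions would differ and are not offered.
* **Group tests**: Student's t defaults to pooled variance (Welch by
  flag); Tukey HSD uses the studentized range via scipy and handles
  unbalanced designs; Kruskal–Wallis applies tie correction. SD and SEM
  use n−1 denominators throughout.

## Pipeline and reproducibility

A cohort study is a pure function of (config, seed): per-cell seeds are
derived from the master seed with `numpy.random.SeedSequence` keyed by a
CRC of the cohort label, so any cell can be regenerated alone and report
files are byte-identical across runs. The demonstration configuration
forces the hypertrophic counts to 1/12 and 13/16 so the contingency —
and its Fisher p-value of 3.41 × 10⁻⁴ — is reproduced end to end through
generation, morphometry and the statistics layer.

## Problem sizes

Defaults were chosen so a full test run and the acceptance script each
finish in minutes on one core: cohorts of 12–16 cells with 150 μm arbors
(60 μm in the fast test overrides), 200 replicate arbors per branch-rate
condition, 100–200 CSR mosaics of 500 points for calibration, DRP
patterns of 1 200–2 000 points, 200 simulated units for classifier
recovery, and 500 units for tuning-recovery statistics. The power check
on branch-point contrasts uses 12 cells per arm over 10 replicates; the
contrast (a doubled branch rate) is large enough that power is ~1.

## What passing tests do not show

The generators reproduce the *statistical structure* the analyses
assume — radially symmetric near-planar arbors, hard-core mosaics, von
Mises–modulated Poisson spiking, Gaussian-band lamination, distally
biased puncta — not the biology: no reconstruction noise or tracing
errors, no soma-size/eccentricity gradients, no correlated firing or
bursting, no optical blur or segmentation artifacts. Passing tests
certify the measurements and their oracles, not any claim about real
tissue. Group-level results other than the hypertrophic contingency
depend on unpublished per-cell data and are deliberately not reproduced.
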