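# Methods

This note documents the models, rules, and numerical choices behind
`synaptomap`: what the synthetic generator emulates, how each pipeline
stage is defined, which parameters matter, and what the validation on
synthetic cohorts does and does not establish about real data.

## Synthetic cohort model

The generator emulates multi-round, multi-channel confocal acquisition of
dissociated hippocampal cultures at an effective pixel size of 187 nm
(0.187 µm/px, configurable).  One field consists of `n_rounds = 10` rounds
of `channels_per_round = 4` channels; MAP2 occupies channel 0 of every
round (it is re-stained and re-imaged each round as the registration
reference), DAPI and the eleven synaptic targets fill the remaining slots,
and leftover slots carry background only.

**Dendrite.**  A smoothed unit-step random walk (heading increments
N(0, 0.12 rad), reflected at a 12-px margin) of length 2.2× the image
width, rasterized at 5 px width.  The skeleton length is recorded
analytically as the walk's step count × pixel size — it is a ground-truth
quantity, not re-measured from the raster.

**Nuclei.**  A soma nucleus at the walk origin plus a Poisson number of
extra nuclei; solid disks (radius 7–11 px) with smooth DAPI falloff.

**Synapses.**  The synapse count is Poisson with mean
(56 + 15.8)/100 µm × skeleton length — the sum of the excitatory and
inhibitory dendritic densities.  Centres are placed uniformly along the
walk with sub-pixel jitter under a hard-core constraint
(`min_synapse_gap_px = 5`, ≈ 0.9 µm) and a 6-px clearance from nuclei:
synapses are discrete ~0.7 µm structures that neither interpenetrate nor
sit on the soma, and the hard core keeps the generated ground truth
resolvable at the stated densities.  Class labels are drawn per synapse:
22 % "unknown" (synapsin1 only), 12 % "dual" (both transporters), the
rest excitatory with probability `ei_ratio/(1+ei_ratio)` (default 5:1).

**Subtype profiles.**  Classified synapses draw one of six profiles —
five excitatory (the dominant one holding 57.9 % of the excitatory mass,
expressing every target at high level; four dimmer variants each lacking
a characteristic pair of scaffold/cytoskeletal proteins; one sparse) and
one inhibitory (vGAT/gephyrin positive, partial scaffold bleed-in).
Presence probabilities are deliberately crisp (≈ 0.97 or ≈ 0.03): each
subtype is a near-binary protein barcode plus a log-normal intensity
level, which makes "how many subtypes are recoverable" a well-posed
question with a known answer of six.  Published per-cluster intensity
heatmaps constrain only the qualitative ordering; the numeric profile
values here are free generator parameters.

**Rendering.**  Each punctum is an isotropic 2D Gaussian truncated at 3σ.
The synapsin1 anchor σ is uniform in [1.05, 1.45] px; children reuse
70–95 % of their anchor's σ (the vesicle pool is the largest structure of
a synapse — and a child larger than its anchor could never satisfy a
child-normalized 50 % overlap rule).  σ ≈ 1 px corresponds to the ~420 nm
lateral resolution of spinning-disk confocal at this pixel size.
Children are offset from the anchor by per-axis N(0, 0.6 px)
(presynaptic) or N(0, 1.3 px) (postsynaptic).  The recorded ground-truth
intensity of a punctum is the actually-rendered kernel sum, so with all
corruptions disabled the images are exact sums of ground truth.  Decoy
puncta (random position and size, some outside the 3–15 px band) are
rendered at a configurable rate and recorded separately to exercise the
size and location filters.

**Corruptions**, applied in acquisition order after scene rendering:
per-round integer translations uniform in ±`shift_range_px` (default 3;
round 0 is the reference and unshifted), one multiplicative planar
illumination gradient per field (amplitude 0.25), a constant background
offset (10), Poisson noise (`img → Poisson(img·s)/s`, s = 0.5), and
additive Gaussian read noise (sd 4).  All randomness flows from
`SeedSequence((seed, replicate, field))`, so any field regenerates
independently and byte-identically.

**Treatment structure.**  Six untreated and five treated replicates
(configurable) of five fields each; treated replicates multiply selected
targets' punctum amplitudes by `treatment_effects[target]`.  A
truth-only path (`generate_truth_cohort`) skips the image pass and is used
to calibrate the statistics layer directly against the generative model.

## Pipeline definitions

- **Alignment**: FFT cross-correlation of each round's MAP2 against round
  0, restricted to integer translations (the generator injects pure
  integer shifts and nothing in the emulated acquisition motivates
  rotation/affine terms).  A featureless MAP2 image is an error naming
  the round.
- **Illumination correction**: subtract a grey-morphology opening with an
  octagonal element of radius 20 px (sequence-decomposed disk; exact for
  locally linear backgrounds, fast).  Puncta-scale structure passes
  through unchanged; residual gradient error is of order slope × radius
  at image borders.
- **Spot enhancement**: white top-hat with an exact disk of radius 4 px
  (puncta are ≤ 15 px across; the element must exceed the largest spot).
- **Thresholding**: per image, discard the dimmest/brightest 5 % of
  pixels and take mean + 2 sd (population sd) of the rest; average the
  per-image values over all *untreated* fields to one threshold per
  target, reused verbatim for treated fields so both groups are segmented
  identically.  With floor-based trim counts at least one pixel always
  survives, so the threshold is always defined.
- **Declumping**: Gaussian pre-smoothing (σ = 1 px), all strict 3×3 local
  maxima inside the thresholded foreground, then brightest-first
  minimum-separation suppression (3 px) and seeded watershed on the
  inverted smoothed intensity.  Suppression is deliberately two-stage: a
  genuine dim maximum on a brighter neighbour's shoulder survives as long
  as it keeps 3 px clearance (a plain "maximum of the whole window"
  detector silently deletes such peaks).  Object counts are monotone
  non-increasing in the threshold for resolved spots; for merging blobs a
  higher threshold can legitimately split one object into two — an
  inherent property of any declumping segmenter.
- **Compartments**: nuclei from smoothed DAPI + Otsu + hole filling +
  small-object removal; dendrites from σ = 1 px smoothed MAP2 +
  robust-background threshold, a 1-px erosion (undoing the smoothing
  dilation), and small-object removal.  The smoothing suppresses boundary
  roughness that otherwise grows spurious skeleton branches and inflates
  dendrite length by ~20 %.
- **Assembly rules** (all boundaries inclusive): equivalent diameter in
  [3, 15] px; no pixel on the nuclei mask; minimum punctum-pixel distance
  to the dendrite mask ≤ 8 px (Euclidean distance transform, edge-based);
  overlap fraction = |child ∩ anchor| / |child|, ≥ 0.50 for presynaptic
  and ≥ 0.0625 for postsynaptic children.  A child joins only the anchor
  with maximal overlap; exact ties go to the smaller anchor label, making
  assembly deterministic.  Anchors themselves must pass the location
  rules.  Classification: vGlut1-only children → excitatory, vGAT-only →
  inhibitory, both → dual, neither → unknown.
- **Features**: area, extent, solidity (hull over pixel centres, so
  digitally convex sets score exactly 1), Euler number (8-connected
  foreground, 4-connected holes), moments-ellipse quantities with the
  1/12 px² finite-pixel correction (keeps eccentricity < 1 for one-pixel-
  wide regions), Crofton 4-direction perimeter, form factor 4πA/P²,
  compactness = mean squared centroid distance / (A/2π) (disk → 1),
  interior-distance radii; intensity statistics with population sd,
  linear-interpolation quartiles, MAD about the median, 4-neighbour edge
  pixels, and mass displacement.  The Crofton estimator was chosen over
  boundary-walk lengths because only it converges to the true perimeter
  for smooth shapes — chain-code and crack-length walks are biased ~5 %
  and ~27 % high on disks, which would cap the form factor of circular
  puncta at ~0.91 and ~0.62 instead of approaching 1.
- **Paper-mode table**: the published 107-entry clustering-input column
  set (the printed list has one duplicated row and one typo, both
  resolved); all-NA columns are dropped and recorded.  Normalization
  divides every intensity-metric column by its untreated-group mean
  (shape, distance, and count columns keep native units); it is
  idempotent.
- **Clustering**: ≤ 2 000 synapses per replicate without replacement;
  findCorrelation-style pruning at |r| > 0.90 (drop the member with the
  larger mean absolute correlation; constant columns first); centre/scale
  with sample sd, parameters retained for held-out rows; UMAP
  (2 components, 15 neighbours, min_dist 0.1, Euclidean, fixed
  random_state — this also pins the single-threaded code path); HDBSCAN
  with min_cluster_size 100, noise = −1, clusters renumbered by
  descending size.
- **Statistics**: the exchangeable unit is the biological replicate.
  Permutation t tests enumerate all C(n₁+n₂, n₁) relabelings exactly
  whenever that count is ≤ the shuffle budget (it is for 6 vs 5:
  C(11,5) = 462), otherwise Monte Carlo with the (count+1)/(n+1)
  convention; the difference CI is a percentile bootstrap.  Cohen's d
  uses the Bessel-pooled sd; its CI is BCa (bias correction from the
  bootstrap fraction below the estimate, acceleration from jackknife
  skewness over both groups).  Power uses the noncentral t with
  ncp = d·√(n₁n₂/(n₁+n₂)), with a limit fallback where the nct
  implementation underflows.  Correlation summaries average per-replicate
  Pearson matrices element-wise (replicates need ≥ 3 synapses; constant
  targets contribute NA and are excluded); entries with |r| < 0.4 are
  masked (|r| = 0.4 is kept); leaf order from average linkage on 1 − r.
  Benjamini–Hochberg-adjusted p values are emitted for information only;
  inference follows the raw permutation p values.
- **Dendrite length**: skeleton pixel count + (√2 − 1) per purely
  diagonal 8-adjacency (pairs not bridged by a shared 4-neighbour).
  A straight 107-px skeleton is 107 px exactly; a 45° run converges to
  √2 per step; axial field tiling splits exactly.

## Validation scope

Problem sizes were chosen so a full check runs on one CPU in minutes:
validation fields are 256×256 px (≈ 48 µm square, ~75 synapses each), the
subtype-recovery cohorts use 11 replicates × 3 fields, the end-to-end
composition check uses ~110 fields (~8 000 synapses), and the statistics
calibration runs on truth-only cohorts (200+ null comparisons).

On these cohorts: alignment recovers every injected integer shift
exactly; zero-corruption fields are recovered at ≥ 95 % recall within
2 px with ≥ 90 % class agreement; the 5:1 excitatory:inhibitory
composition is recovered within 10 % from rendered images (the residual
~2 % downward bias is real pipeline behaviour — transporter children that
fail the 50 % overlap rule demote excitatory synapses to unknown);
UMAP + HDBSCAN reports the six injected subtypes in ≥ 8 of 10 seeded runs
with ≥ 80 % contingency agreement; an injected 1.5× single-target effect
is detected at p < 0.05 in ≥ 8 of 10 cohorts while the null battery
rejects at 1–15 %.

What passing these tests does **not** show: the generator renders
isotropic Gaussian puncta with crisp per-subtype presence barcodes, no
axons or glial background, no antibody cross-reactivity, no
round-to-round bleaching, and misalignment restricted to integer
translations.  Real tissue violates all of these; on real data the
pipeline's absolute recall, the recovered cluster count, and the
unknown/dual fractions would depend on staining quality and optics, and
cluster structure would be far less discrete.  The tests establish that
the implementation applies the stated rules exactly and recovers known
structure when the data match its assumptions — not that six subtypes is
the answer for any particular culture.

## Known limitations

- Subpixel and rotational misregistration are out of scope (the
  registration model is integer translation).
- The anchor-merging regime (synapses closer than ~3 px) is excluded by
  the generator's hard core; behaviour under heavy merging is untested.
- HDBSCAN's `min_cluster_size` is an absolute count, so the reported
  cluster number is scale-dependent: the generator's discrete subtype
  islands yield six clusters at the ~2000-synapses-per-replicate analysis
  scale but fragment into sub-clusters when several times more rows are
  pooled. Replicate-balanced subsampling is therefore part of the
  analysis contract, not just a convenience.
- BCa coverage for n ≈ 20 replicate-level samples runs ~92–93 % at
  nominal 95 %, the usual small-sample behaviour of BCa.
- The CLI stage subcommands recompute prerequisite stages in memory from
  the manifest rather than caching intermediate images; only each stage's
  own CSV artifacts are written.
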