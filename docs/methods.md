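# Methods

This note documents the models, parameter choices, numerical
conventions and known limitations behind `synaptostats3d`. Units are
nanometres (nm), nm², and synapses/µm³ throughout; boxes are 0-based
and half-open, `[0, extent)` per axis.

## Synthetic data generator

The generator emulates the measured structure of human hippocampal CA1
neuropil so that every downstream stage can be validated against known
ground truth.

**Layer profiles.** The packaged `data/layer_profiles.yaml` transcribes,
for the five layers (SO, dSP, sSP, SR, SLM): the corrected mean
synaptic densities (0.45–0.99 synapses/µm³), the AS percentage (about
95:5 AS:SS everywhere except SLM, where it is about 90:10), and the
corrected SAS-area mean ± sem with the per-layer synapse counts.

**Positions** are homogeneous Poisson (CSR): the count is
Poisson(λ·V) and coordinates are i.i.d. uniform in the box. Hard-core
(simple sequential inhibition) and Thomas cluster generators provide
non-CSR alternatives for power checks. Synapse centroids stand in for
whole reconstructed junctions, so "distance" always means
centroid-to-centroid.

**SAS areas** follow a log-normal per polarity, calibrated by method of
moments: the SD is recovered as sem·√n from the transcribed summary, and
then σ² = ln(1 + (SD/mean)²), µ = ln(mean) − σ²/2. The per-layer
distribution parameters themselves were not published, so this
calibration is an approximation that matches the first two moments
exactly. A log-logistic with CDF 1/(1 + (x/α)^−β) is offered as the
alternative family.

**Declared calibration choices** (not measured values): the AS
horseshoe/fragmented split (4.50%/1.42% of the 5.92% remainder after
macular 85.95% and perforated 8.13%) and the SS perforated/fragmented
split (4.50%/3.01%); the spiny/aspiny shaft splits (0.55 for AS, 0.60
for SS); perimeter scaling P = c·√A·lognormal(0, 0.2) with c set from
the pooled mean perimeter over √(mean area) (4.87 for AS, 5.32 for SS);
and a Beta curvature mark with means 0.050 (AS) / 0.047 (SS) and
concentration 24. The pooled target multinomials (identified-target
fraction, spine share, head share) are applied to every layer because
per-layer breakdowns are not part of the transcription.

**Parametric SAS meshes** come from five families with closed-form
area, perimeter, curvature and topology: disk, spherical cap (curvature
h/2R, so a hemisphere is 0.5), annulus, open annular band (horseshoe)
and a set of disjoint disks (fragmented). Each mesh is placed in a
seeded random rigid pose so that measurement invariance is exercised.

**Artifact masks and semithin label images** are quantile-thresholded
Gaussian-smoothed noise fields. Thresholding at exact quantiles pins
the occupied voxel/pixel shares to the targets (well within the ±0.01
and ±0.5-point contracts) while keeping blob-like spatial structure;
the blob shape itself is irrelevant to the point-counting arithmetic
downstream.

**What the generator does not emulate:** raw EM contrast, membranes and
segmentation ambiguity; anisotropic or inhomogeneous synapse intensity
within a stack; between-case variance beyond Poisson/binomial sampling
(all stacks of a layer share one profile); spatial correlation between
marks (size, shape) and position. Passing tests therefore validate the
measurement chain, not biological inference from real tissue.

## Stereology and corrections

Grid points are laid at spacing √a from a configurable origin; a point
landing exactly on a pixel boundary takes the pixel at
floor(coordinate), which keeps the assignment deterministic under the
half-open convention. The artifact fraction of a stack is
point-counted on every 20th section by default (falling back, with a
warning, to the middle section of very shallow stacks).

Shrinkage factors are ratios of processed to fresh measurements:
p² = A_post/A_pre in-plane, p = √p², p_z = t_post/t_pre axially, and
s_vol = p²·p_z. Swelling (post > pre) warns but still computes the
ratio. Corrections: length ℓ/p, area A/p², volume V(1 − f)/s_vol, and
density λ·s_vol/(1 − f). The artifact discount is applied to the
measured volume *before* the shrinkage division because the artifact is
measured in the processed tissue. Reported values are rounded half-up
to two decimals; all internal arithmetic is full precision. Note that
restoring a length with the 3-decimal p = 0.966 and with √0.933
differ in the second decimal of large values — the package computes
with whatever factor object it is given and leaves the rounding
convention to the caller.

The corrected/uncorrected counting-frame volume pairs of the source
material cannot be reproduced by s_vol alone or by s_vol with any
single artifact fraction, because the per-stack artifact fractions were
never published; the package exposes both volume conventions and takes
no position on that composition.

## Counting frame

The brick rule is fixed with exclusion faces at minimum-x/y/z and
inclusion faces at the maxima (the rule requires an orientation; this
one is a convention, declared in every output sidecar). With only
centroids available the rule degrades to centroid-in-box with open
boundaries on the exclusion faces: a centroid exactly on an exclusion
face is discarded, one exactly on an inclusion face is kept. The
sidecar records the rule so mesh-based full-extent filtering can be
distinguished later. Unbiasedness is verified by Monte-Carlo: the mean
density over 200 random frame placements on CSR data recovers the true
intensity within 3 SE.

## Spatial statistics

Estimators use reduced-sample (minus-sampling) border correction: at
radius r only points (or empty-space test locations) farther than r
from every window face contribute. The F-function test grid is a
regular lattice of ⌈n^(1/3)⌉³ cell centers. The default radius grid is
50 values from 0 to one quarter of the shortest window edge; the
reduced-sample ratio is not automatically monotone, so curves are
post-processed with a running maximum to present proper CDFs. Pair
counts for K use an O(n²) compiled kernel, checked exactly against a
naive distance-matrix oracle on small instances.

**Envelope construction.** Two styles are provided. The *pointwise*
style takes the per-radius min/max of the simulated curves; its
per-radius two-sided level is 2/(n_sim + 1), but a verdict that
requires the observed curve to stay inside at *every* radius compounds
across the grid: measured on CSR input (n = 1000, 10 µm cube, default
grid) the pointwise verdict falsely rejects about 20% of the time for
both G and K. The default is therefore the classical
maximum-absolute-deviation *global* envelope: a band of constant
half-width D around the CSR theoretical curve, where D is the largest
deviation of any simulated curve from theory. Because the observed
deviation is exchangeable with the simulated ones under CSR, the
verdict's false-alarm rate is exactly 1/(n_sim + 1) — 1% with the
conventional 99 simulations — independent of the grid. Measured
calibration: 100/100 CSR patterns accepted, 100/100 hard-core patterns
rejected by G, 100/100 strongly clustered (Thomas) patterns rejected by
K. F/G bands are clipped to [0, 1] and K bands to nonnegative values.

Envelope simulations condition on the observed count n (binomial
patterns), the standard conditioning for CSR envelope tests.

## SAS morphometry

Area is the sum of triangle areas; perimeter is the total length of
boundary edges (edges incident to exactly one triangle), covering outer
and hole loops of every component. Components are connected components
of the vertex graph restricted to triangles; loops are connected
components of the boundary-edge graph, and interior holes are loops
minus one per open component.

The projection plane is the area-weighted orthogonal-regression plane
(eigen-decomposition of the area-weighted vertex covariance); the
projected area is the area of the *union* of projected triangles, not
their sum, so folded sheets are not double counted. Curvature
1 − projected/total is clamped to [0, 1). Near-collinear vertex sets
(second covariance eigenvalue ≤ 1e-12 of the first) are rejected
because no plane is defined.

The shape cascade is: ≥ 2 components → fragmented; ≥ 1 hole →
perforated; projected-outline solidity (outline area over its convex
hull) < 0.85 → horseshoe; else macular. The 0.85 threshold is declared,
not inferred — the original classification was visual — and is a
parameter of `classify_shape`. On the parametric families the
classifier is exact (200/200 seeded fixtures), which shows the cascade
is self-consistent, not that it reproduces human judgements on real
surfaces.

## Statistics

The χ² statistic is authored directly from E_ij = T_i·T_j/T with no
continuity correction, and cross-checked against an independent library
implementation. Mann-Whitney uses the exact permutation null for
tie-free samples with both n ≤ 8 (verified to 1e-9 against exhaustive
rank enumeration) and the tie-corrected normal approximation otherwise.
ANOVA is classical (not Welch) — the variance-homogeneity question was
left open in the source methodology, and classical is what the listed
software defaults to — with Tukey HSD pairwise comparisons. Log-normal
fits use the closed-form MLE on logs; log-logistic fits are numerical
MLE with the scale-α/shape-β parameterization stated above. Model
comparison uses AIC = 4 − 2·logL.

The dual-threshold convention is applied from the declared basis of
each analysis: α = 0.05 for subject-level tests (ANOVA, MW), α = 0.001
for synapse-level tests (χ², KS). Pairwise layer comparisons run as
2-column sub-tables at the synapse-level α with no further
multiple-testing correction, matching the source convention of using
the stricter α instead. Null-simulation calibration (1000 runs per
test) keeps empirical type-I error inside binomial 99% bands at both
thresholds.

## Pipeline problem sizes and defaults

The desk-scale study uses 5 cases × 3 stacks per case per layer with a
10.24 × 7.68 × 5 µm stack (the in-plane footprint of the acquisition
field of view), a 400 nm counting-frame margin, and CSR envelopes with
99 simulations on one stack per layer — about 20,000 generated synapses
in total, running in a few seconds. Densities are summarised as mean ±
SD over case aggregates (counts and volumes summed within case), with
pooled values from summed counts and volumes; percentages round half-up
to 2 decimals and thickness shares to integers. Shrinkage factors
default to identity so recovered values compare directly with generator
ground truth; pass measured factors to exercise the correction path.
Every output table is byte-reproducible from the seed.

## Known limitations

* Centroid-based counting-frame filtering cannot implement the
  full-extent brick rule (a junction touching an exclusion-face
  extension is only excluded if its centroid is); the output sidecar
  flags the rule used.
* Whether a synapse touching an inclusion face while extending outside
  the stack should count cannot be decided from centroids; the open
  inclusion-boundary convention above is the declared choice.
* The morphometry module takes meshes as given; it does not extract
  SAS surfaces from voxel segmentations.
* Spatial analysis is marginal CSR only: no inhomogeneous intensity,
  pair-correlation function, or cross-type (AS vs SS) mark correlation.
* The log-logistic numerical MLE can warn on pathological samples;
  fits are always validated by the returned KS distance.
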