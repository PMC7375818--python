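# synaptostats3d

Quantitative analysis toolkit for 3D electron-microscopy synapse studies
of the kind performed with FIB/SEM serial imaging of cortical and
hippocampal neuropil: stereological volume fractions, synaptic densities
from unbiased 3D counting frames with shrinkage and fixation-artifact
corrections, spatial point-pattern tests against complete spatial
randomness (CSR), synaptic-apposition-surface (SAS) morphometry, and the
accompanying statistical battery. A first-class synthetic-data module
generates populations, surfaces, masks and label images with known
ground truth, so every stage is testable without any imaging data.

It is written for neuroanatomists and image-analysis engineers who
quantify synapses in volume EM, and for methodologists who want a
reference implementation of the standard measurement chain.

## What it computes

**Stereology.** Volume fractions by Cavalieri point counting: a square
grid with area-per-point *a* is overlaid on a label image and
V_v(class) = hits/total x 100; a designated remainder class (neuropil)
is obtained as V_v = 100 − Σ V_v(others). The same counting on every
*k*-th section of a binary stack estimates the fixation-artifact volume
fraction.

**Corrections.** Tissue processing shrinks the specimen. From pre/post
measurements the package derives the in-plane area factor p² (and
p = √p²), the section-thickness factor p_z, and the volume factor
s_vol = p²·p_z. Lengths are restored as ℓ/p, areas as A/p², volumes as
V·(1 − f_artifact)/s_vol, and densities as λ·s_vol/(1 − f_artifact).

**Counting.** The unbiased 3D counting frame (brick rule) with
exclusion faces at the minimum-x/y/z planes; synaptic density is the
included count over the (optionally corrected) frame volume.

**Spatial statistics.** The empty-space function F, nearest-neighbour
function G and Ripley's K in 3D with reduced-sample border correction,
compared against the CSR references F(r) = G(r) = 1 − exp(−λ·4πr³/3)
and K(r) = 4πr³/3 through Monte-Carlo envelopes (99 CSR simulations by
default). The default verdict uses the maximum-absolute-deviation
*global* envelope, whose false-alarm rate is exactly 1/(n_sim + 1).

**Morphometry.** For a triangulated SAS: area (Σ triangle areas),
perimeter (total boundary-loop length), curvature
1 − projected_area/area with the projection on the best-fit plane, and
the four-way shape classification — fragmented (≥ 2 components),
perforated (≥ 1 interior hole), horseshoe (indented outline, solidity
below 0.85), macular otherwise.

**Statistics.** χ² tests of association with E_ij = T_i·T_j/T,
two-sample Kolmogorov–Smirnov, Mann–Whitney U (exact for small
samples), one-way ANOVA with Tukey HSD, log-normal and log-logistic
maximum-likelihood size-distribution fits, and R². Significance uses a
dual-threshold convention: α = 0.05 when the sampling unit is the
subject, α = 0.001 when it is the individual synapse.

## Worked example

```python
import numpy as np
import synaptostats3d as s3d

# 1. a synthetic stack from the stratum oriens profile
geom = s3d.StackGeometry(10_240, 7_680, 5_000)            # nm
profile = s3d.load_layer_profiles()["SO"]
pop = s3d.generate_population(geom, profile, seed=7)

# 2. unbiased counting frame and density
frame = s3d.CountingFrame.from_stack(geom, margin=400.0)
included, meta = s3d.counting_frame_filter(pop, frame, geom)
dens = s3d.synaptic_density(meta["n_included"], frame.volume_um3)

# 3. correction arithmetic with the measured shrinkage factors
corr = s3d.apply_correction(dens.density_per_um3, "density",
                            s3d.STUDY_FACTORS, artifact_fraction=0.1)

# 4. CSR test on the synapse centroids
pat = s3d.PointPattern(
    included[["cx_nm", "cy_nm", "cz_nm"]].to_numpy() - np.asarray(frame.lo),
    s3d.StackGeometry(*(np.asarray(frame.hi) - np.asarray(frame.lo))))
env = s3d.csr_envelope(pat, "G", n_sim=99, seed=1)

# 5. SAS morphometry on a parametric surface
mesh, truth = s3d.generate_sas_mesh(
    s3d.SasShapeSpec("spherical_cap", {"radius": 600.0, "height": 600.0}), seed=2)
res = s3d.measure(mesh)
```

This prints:

```
generated 182 synapses, 137 inside the frame
raw density: 0.5 synapses/um^3 (profile ground truth 0.45)
density corrected for shrinkage and a 10% artifact volume: 0.47
G function within 99-simulation CSR envelope: True
hemisphere SAS: curvature 0.500 (closed form 0.5), class macular
```

The 182 generated synapses are a Poisson draw at the layer's 0.45
synapses/µm³ intensity; 137 survive the brick rule, giving a raw
density of 0.50/µm³ in the 273 µm³ frame — within sampling error of
the ground truth. Correcting for shrinkage (p² = 0.933, p_z = 0.901)
and a 10% artifact volume rescales it to 0.47/µm³. The centroids pass
the CSR test (they were generated CSR), and the hemisphere's curvature
1 − πR²/2πR² = 0.5 is recovered to three decimals.

The full study — every layer, five cases, three stacks each, the
Table-style per-layer summary, CSR verdicts, proportion tables and the
statistical battery — runs from one seed:

```bash
synaptostats3d run --seed 3 --out report/
```

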