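# Per-layer generative profiles for the human CA1 synthetic populations.
#
# Transcribed study conditions per layer: corrected mean synaptic density
# (synapses/um^3), AS percentage, and corrected SAS-area mean +/- sem with
# the per-layer synapse counts (the size SD is recovered as sem*sqrt(n) and
# a log-normal is calibrated by method of moments).
#
# Postsynaptic-target and shape multinomials are pooled over layers: the
# per-layer breakdowns live in a supplementary file that is not part of the
# transcription, so the pooled conditional proportions (identified-target
# fraction, spine-vs-shaft split, head-vs-neck split) are applied to every
# layer.  The AS horseshoe/fragmented split and the SS perforated/fragmented
# split, the spiny/aspiny shaft splits, and the perimeter scaling factors are
# declared calibration choices (see docs/methods.md), not measured values.

targets_pooled: &targets
  AS:
    identified_fraction: 0.4658     # 8449 of 18138 AS with identifiable target
    spine_given_identified: 0.8722
    head_given_spine: 0.995
    spiny_given_shaft: 0.55
  SS:
    identified_fraction: 0.8780     # 993 of 1131
    spine_given_identified: 0.1007
    head_given_spine: 0.82
    spiny_given_shaft: 0.60

shapes_pooled: &shapes
  AS: {macular: 0.8595, horseshoe: 0.0450, perforated: 0.0813, fragmented: 0.0142}
  SS: {macular: 0.8055, horseshoe: 0.1194, perforated: 0.0450, fragmented: 0.0301}

perimeter_pooled: &perimeter
  AS: 4.870        # mean perimeter / sqrt(mean area), pooled
  SS: 5.316

layers:
  SO:
    intensity: 0.45
    as_fraction: 0.9410
    sas_area:
      AS: {mean: 86716.52, sem: 1371.02, n: 2648}
      SS: {mean: 85737.60, sem: 5869.60, n: 166}
    targets: *targets
    shapes: *shapes
    perimeter_factor: *perimeter
  dSP:
    intensity: 0.69
    as_fraction: 0.9320
    sas_area:
      AS: {mean: 92045.29, sem: 1192.92, n: 3849}
      SS: {mean: 74764.69, sem: 3057.33, n: 281}
    targets: *targets
    shapes: *shapes
    perimeter_factor: *perimeter
  sSP:
    intensity: 0.99
    as_fraction: 0.9636
    sas_area:
      AS: {mean: 88061.63, sem: 1038.49, n: 5183}
      SS: {mean: 58305.43, sem: 2612.01, n: 196}
    targets: *targets
    shapes: *shapes
    perimeter_factor: *perimeter
  SR:
    intensity: 0.67
    as_fraction: 0.9571
    sas_area:
      AS: {mean: 82841.26, sem: 1201.47, n: 3836}
      SS: {mean: 63183.20, sem: 2734.96, n: 172}
    targets: *targets
    shapes: *shapes
    perimeter_factor: *perimeter
  SLM:
    intensity: 0.52
    as_fraction: 0.8924
    sas_area:
      AS: {mean: 91419.95, sem: 1376.38, n: 2622}
      SS: {mean: 57390.19, sem: 2071.04, n: 316}
    targets: *targets
    shapes: *shapes
    perimeter_factor: *perimeter
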