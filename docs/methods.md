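# Methods

## Scoring model

A cell's damage readout is the number of discrete γH2AX foci in its
nucleus, scored only for cells whose cycle state makes the count
interpretable. The validity rule is conjunctive:

1. **pericentrin count ∈ {1, 2}** — pericentrin is a constitutive
   centrosomal marker: one spot through G1/S, two after centrosome
   splitting in late G2/M. Zero detected spots mean the marker was
   missed (the spot can sit outside the nuclear outline); three or more
   mean the "nucleus" is probably two touching nuclei. Both cases
   invalidate the cell rather than contribute a possibly doubled focus
   count. Dropped cells are tallied in the QC block; excluding
   zero-pericentrin cells can slightly over-score the mean, since those
   are disproportionately zero-focus cells.
2. **nuclear area in the G1 or G2 gate** — area in "points"
   (`points = pixels × points_scale`) is partitioned at 50 / 130 / 250:
   below 50 is debris, 50–130 G1, 130–250 G2, above 250
   overlapped/polyploid and rejected. The gate boundary 130 is assigned
   to G2 and 250 is inclusive (G2-marker-positive cells are observed at
   both extremes of the 130–250 range); 50 is assigned to G1.
3. **interphase staining pattern** — pan-nuclear S/M patterns carry no
   countable foci (see below).

Valid cells receive a class group, the pair (pericentrin count, focus
count capped at 10); the cross product {1,2} × {0..10} gives 22
mutually exclusive groups.

### Gate calibration

`calibrate_area_gates` reproduces the calibration procedure: score a
population labelled with a G2 marker (CENP-F accumulates through G2/M),
take the observed min and max of the labelled areas as the G1/G2 and
rejection gates, and report the mean labelled area. With labelled areas
uniform on [130, 250] the extremes converge to the gates at rate
120/(n+1), so n = 500 recovers both within a fraction of a point.

### Pan-nuclear pattern flags

On the background-subtracted γH2AX max projection we compute, per
nucleus, the supra-threshold **coverage** (fraction of nuclear pixels
above the detection threshold) and the **CV** of the supra-threshold
signal. Uniform bright staining (coverage > 0.8, CV < 0.6, or high
coverage with two pericentrin spots) flags M; rough granular staining
(coverage > 0.5, CV ≥ 0.6) flags S; anything else is interphase. The
cuts are configuration defaults validated against the synthetic
patterns (each ≥95% correct on 200 rendered cells); on real data they
would need re-tuning because the source description of the patterns is
qualitative.

## Spot detection

Per z-plane: subtract the plane median (background), threshold at the
per-channel detection threshold, label the connected footprint, and
keep components that contain a difference-of-Gaussians local maximum
and at least `min_spot_px` pixels. Fragments in adjacent planes are
union-merged when their xy-centroids fall within
max(merge radius, half the larger fragment's diameter); the default
merge radius is one reference diameter. A spot spanning several planes
is therefore counted once; its intensity extrema are taken over the
whole merged footprint and its integrated intensity is the
background-subtracted sum.

Two deliberate behaviors:

* **overlap merging is preserved, not corrected** — two foci whose
  footprints connect at threshold return as one spot. This is the
  mechanism behind count saturation at high dose (foci grow and crowd
  with dose), and the pipeline is expected to reproduce that bias.
* **maximum-diameter acceptance** — a spot is accepted iff
  `diameter ≤ reference_diameter × spot_diameter_pct / 100` (default
  280%, boundary inclusive). This is interpreted as a maximum-size
  classifier in the style of FISH signal filters; it also discards the
  whole-nucleus "spot" a pan-nuclear M cell produces.

Thresholds are fixed per run — the acquisition contract is constant
exposure and camera settings — and never auto-adapted per field.

Nucleus segmentation is an Otsu threshold on the DAPI max projection
with hole filling and a minimum-size prefilter at the debris gate.
Watershed splitting of touching nuclei is deliberately absent: the
pericentrin count and the >250-point gate reject merged objects, which
is the point of the co-staining design. Pericentrin spots are assigned
to nuclei after label dilation (default 6 px) because the centrosome
sits at the nuclear periphery, often just outside the DAPI outline.

## Synthetic fixtures

The generator emulates an exponentially growing human mammary
epithelial culture imaged at 60× as 4-plane z-stacks, 2.1 µm apart, in
three 16-bit channels on a 1392×1040 field. Defaults (all in
`GeneratorConfig`):

| parameter | default | rationale |
|---|---|---|
| control focus rate | 1.12 foci/cell | observed control mean |
| focus rate slope | 7.26 /Gy | reproduces the 4.75 foci/cell mean at 0.5 Gy |
| G2 focus multiplier | 2.0 | doubled DNA/histone content; no quantitative source, qualitative ordering only |
| G2 fraction | 0.16 | big-area fraction in growing culture |
| S fraction | 0.24 | BrdU-positive fraction after a 30-min pulse |
| M fraction | 0.02 | typical mitotic index |
| G1 / G2 area ranges | 55–125 / 135–248 points | inside the 50–130 / 130–250 gates with a margin for measurement error |
| focus diameter | 6 px + 2 px/Gy | foci visibly widen with dose |
| focus peak intensity | 600 + 900/Gy counts | brightest-focus intensity rises ~linearly with dose |
| pericentrin–area Spearman | 0.4942 | observed rank correlation |
| points_scale | 0.02 points/px | puts G1 nuclei at ~30–45 px radius, plausible for 60× |
| noise | additive Gaussian, σ = 25 counts | camera read noise scale |

The dose law is linear; the observed sub-linear 1 Gy mean
(5.23 foci/cell) is treated as an emergent consequence of overlap
merging, not a rate-law parameter. Reproduction runs that target the
observed per-dose means pass them as explicit rate overrides.

Foci are isotropic 3-D Gaussians (axial σ 1.7 µm) sampled onto the four
planes; there is no attempt at a real PSF, chromatic aberration or
illumination fields — the generator exists to exercise the detection
and gating logic, so passing tests demonstrate algorithmic correctness
on controlled structure, not performance on real microscope data.
With overlap disabled, foci keep a pairwise separation of 2.3
diameters (best-candidate sampling), which keeps threshold footprints
disjoint so ground-truth counts are exactly recoverable; with overlap
enabled, placement is uniform and merging occurs naturally.

Nuclear area and pericentrin integrated intensity are coupled through a
Gaussian copula on ranks (Pearson ρ = 2 sin(π ρ_s / 6) on the latent
normals). The target correlation is induced exactly on the latent pair
(residual orthogonalization), so a generated sample carries the
configured Spearman within ~±0.01 at n = 1000 rather than a draw with
SD ≈ 0.024 around it; the copula is the generating mechanism, the
induction is variance reduction.

S-phase cells render a sub-threshold pan-nuclear wash plus dense
heavy-tailed granules (one per ~55 px², lognormal amplitudes), giving
>60% coverage with high CV; M cells render a uniform bright wash and
two separated pericentrin spots. Pattern cells carry no countable foci
in the ground truth.

Layout places nuclei on a jittered grid sized by the largest nucleus,
so masks never touch; a touching mode instead places a configured
fraction of cells as overlapping pairs to exercise the rejection path.
Everything is reproducible from the config seed, with per-dose
substreams.

## Statistics

* Mean foci/cell is reported over valid cells with the capped count
  (the 0–10 class scale); the cell-level SE is SD/√n. Capping biases a
  Poisson(5.23) mean down by ~0.03, well inside sampling error at
  n = 1000.
* Mean brightest-focus intensity averages the per-cell maximum
  `intensity_max` over valid cells with ≥1 focus — a zero-focus cell
  has no brightest focus, and including zeros would distort the linear
  intensity–dose relation.
* Mann-Whitney U (two-sided, midranks) uses full enumeration of group
  assignments when both groups have ≤8 observations — p is twice the
  smaller tail, capped at 1, matching the standard permutation
  convention under ties — and the tie-corrected normal approximation
  otherwise. No multiple-testing correction is applied.
* Dose–intensity and manual-vs-automatic agreement are ordinary least
  squares (slope, intercept, r²); the pericentrin–area correlation is
  Spearman's rank correlation restricted to single-pericentrin cells.

## Problem sizes and numerical choices

The reproduction script and acceptance tests use the study's scale:
1000 cells per dose for dose-mean recovery, repeatability and the rank
correlation, 2000 cells per dose for the intensity–dose fit, 500
labelled areas for gate calibration. Unit tests run the same code on
smaller fields (typically 60–200 cells) chosen to keep the full suite
fast while preserving every code path. Degenerate inputs fail loudly:
empty labelled-area lists, zero valid cells (QC error with a tally),
non-positive areas, unknown channels, and mismatched stack geometry all
raise.

## Known limitations

* The pixel→points conversion of the original acquisition system is
  proprietary; only linearity is implemented, with a configurable
  scale.
* The S/M pattern thresholds are validated only against the synthetic
  patterns.
* Focus detection has no sub-pixel PSF fitting or 3-D deconvolution;
  axial merging uses centroid proximity, so two foci stacked exactly
  on the optical axis in different planes would merge.
* Saturation is reproduced, not corrected: at high dose the recovered
  mean undercounts by design, and the recommended mitigation is
  restricting analysis to the G1 stratum.
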