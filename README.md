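# focicount

Automated γH2AX focus counting with cell-cycle sorting for fluorescence
z-stack microscopy.

## The problem

Phosphorylated histone H2AX (γH2AX) forms discrete nuclear foci at DNA
double-strand breaks, so counting foci per nucleus is the standard
microscopy surrogate for radiation-induced DNA damage. Two artifacts
plague automated counts:

* **cell-cycle background** — S-phase cells show a rough pan-nuclear
  γH2AX wash from replication forks, M-phase cells a uniform bright
  stain, and G2 nuclei carry roughly double the focus background of G1
  (doubled DNA/histone content);
* **touching nuclei** — two adjacent nuclei segmented as one object
  inflate the apparent focus count.

`focicount` implements a scoring strategy that addresses both with a
constitutive co-stain, **pericentrin** (one centrosomal spot in G1/S,
two after centrosome splitting in late G2/M), combined with
**nuclear-area gating**: nuclear area in "points" (a linear rescaling of
pixel area) is partitioned at calibrated gates

```
area < 50          -> debris
50  <= area < 130  -> G1
130 <= area <= 250 -> G2
area > 250         -> overlapped nuclei / polyploid (rejected)
```

A cell enters scoring only if it has 1–2 pericentrin signals, a G1/G2
area, and discrete (not pan-nuclear) γH2AX staining; focus counts are
capped at 10, giving the (pericentrin, foci) class groups. Zero
pericentrin signals mean the cell was not captured; three or more mean
presumed touching nuclei — both invalidate the cell instead of
contributing a wrong count.

The package covers the full chain:

* `fixtures` — synthetic 3-channel (DAPI / γH2AX / pericentrin) 4-plane
  z-stack generator with per-cell ground truth: Poisson focus counts
  with mean `λ(D) = λ0 + k·D` (control rate 1.12 foci/cell), focus size
  and peak intensity growing with dose, a Gaussian copula coupling
  pericentrin intensity to nuclear area (Spearman 0.4942), and rendered
  S/M staining patterns;
* `nuclei` — Otsu segmentation on the DAPI max projection, area in
  points (no watershed splitting: merged objects are rejected by the
  pericentrin/area gates downstream);
* `spots` — per-plane difference-of-Gaussians seeding plus
  threshold-connected footprints, merged across adjacent z-planes;
  overlapping foci merge into one spot (the mechanism behind count
  saturation at high dose), and a maximum-diameter acceptance at 280%
  of the reference spot size rejects pan-nuclear blobs;
* `classify` — area gates, pan-nuclear S/M pattern flags, validity and
  class groups, plus gate calibration from a labelled G2 population;
* `stats` — per-sample focus distributions (optionally stratified by
  G1/G2), Mann-Whitney dose comparisons (exact for small groups),
  brightest-focus-intensity vs dose regression, pericentrin–area
  Spearman correlation, repeatability and manual-agreement fits;
* `cli` — `focicount simulate | score | report | calibrate-gates`.

## Worked example

```python
from focicount import (AreaGates, CaptureSettings, GeneratorConfig,
                       generate_sample, score_sample, compare_doses)

cfg = GeneratorConfig(doses_Gy=(0.0, 0.5), cells_per_dose=200, seed=42)
settings, gates = CaptureSettings(), AreaGates()

samples = {}
for dose in cfg.doses_Gy:
    fields, truth = generate_sample(cfg, dose)       # rendered z-stacks + truth
    cells, result = score_sample(fields, settings, gates,
                                 dose_Gy=dose, minimum_nuclei=100)
    samples[dose] = (cells, result)
    print(f"{dose:3.1f} Gy: {result.n_valid_cells} valid cells, "
          f"mean {result.mean_foci:.2f} +/- {result.se_foci:.2f} foci/cell")

u, p = compare_doses(samples[0.0][0], samples[0.5][0])
print(f"Mann-Whitney U = {u:.0f}, p = {p:.2e}")
```

Output:

```
0.0 Gy: 149 valid cells, mean 1.21 +/- 0.10 foci/cell
0.5 Gy: 153 valid cells, mean 5.64 +/- 0.20 foci/cell
Mann-Whitney U = 966, p = 1.10e-43
```

The 0 Gy mean sits near the configured 1.12 foci/cell control rate and
the 0.5 Gy mean near 1.12 + 7.26·0.5 ≈ 4.75; the mild excess comes from
the doubled G2 background in the default phase mixture. Invalid cells
(S/M patterns, missing pericentrin, out-of-gate areas) are excluded
from the means and tallied in `result.qc`.

The same flow runs from the shell:

```bash
focicount simulate --config generator.yaml --out data/
focicount score --input data/dose_0.5Gy --out scored/d05
focicount report scored/d0 scored/d05 --out report.json
```

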