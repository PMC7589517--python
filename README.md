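# bactoline

Analysis toolkit for **in-droplet single-antibody bioassays**: phenotyping
antibody-secreting cells (Ig-SCs) by the apparent affinity (*K*<sub>D app</sub>)
and epitope density of their secreted antibody against a bacterial surface.

In the assay this package models, single B-lineage cells are encapsulated in
~50 pL droplets together with a magnetic nanoparticle aggregate coated with
heat-killed bacteria (a *bactoline*) and a fluorescent anti-Ig detection
probe. Secreted antibody binds surface epitopes; probe bound to
bactoline-anchored antibody concentrates on the aggregate, and the
fluorescence **relocation** R (on-aggregate over background intensity,
baseline 1) is imaged every 15 min for an hour. Relocation first rises with
accumulating antibody and then falls again once epitopes saturate and excess
antibody titrates the probe away — the *Hook effect* of homogeneous
immunoassays. The curve maximum *y*<sub>max</sub> reports epitope capacity;
its position *x*<sub>max</sub> shifts with affinity. The per-droplet feature

&nbsp;&nbsp;&nbsp;&nbsp;α = *y*<sub>max</sub> / (*x*<sub>max</sub> · SR · corr)

(peak height over the antibody concentration accumulated at the peak, using
the cohort-median secretion rate SR) is mapped log-linearly to
*K*<sub>D app</sub> = exp((α − β₀)/β₁), and cells are classified into a 3×3
grid: affinity high (<10 nM) / intermediate (10–50 nM) / low (>50 nM) ×
epitope availability low (*y*<sub>max</sub> < 2) / intermediate (2–3) /
high (>3).

The package provides, for users analysing such screens or studying their
statistical behaviour:

- `bactoline.model` — closed-form mass-action equilibrium of the
  relocation signal (ligand-depletion quadratics for antibody–epitope and
  probe–antibody binding), titration curves, and secretion time traces;
- `bactoline.calibration` — the affinity map (published preset constants
  0.969/−0.014 and refitting from calibrant titrations), the linear
  *y*<sub>max</sub>→epitope map, and the class assignments;
- `bactoline.pipeline` — bactoline segmentation on pixel grids
  (brightest-pixel mask, half-area fragment removal), relocation readout,
  trace features with the interior-maximum rule, α/K_D estimation, cell
  records, and secretion-rate utilities;
- `bactoline.elisa` — kinetic-slope readout, Hill fits and the Beatty
  two-density affinity estimator with plateau-based capacity;
- `bactoline.repertoire` — Poisson-occupancy cell counting, Ig-SC
  frequencies, class-switch ratios, specific/cross-reactive fractions, 3×3
  heat maps with marginals and differences, pooled-variance Student t-tests;
- `bactoline.simulate` — ground-truth generators for droplet populations
  (Poisson occupancy, log-normal secretion rates, configurable 3×3
  affinity×epitope mixtures, bacteria-count variability, multiplicative
  noise), calibration titrations, ELISA plates and rendered droplet images.

## Worked example

Simulate a screen of 5,000 droplets, analyse every trace, and compare the
assigned bins with the generator's ground truth (`examples/03_droplet_screen.py`):

```
droplets: 5000, secreting cells: 464
exclusion breakdown:
no_cell                3862
no_increase             674
(processed)             274
no_interior_maximum     190

affinity x epitope-density heat map (fractions of processed cells):
                low  intermediate   high    sum
high          0.142         0.245  0.504  0.891
intermediate  0.106         0.004  0.000  0.109
low           0.000         0.000  0.000  0.000
sum           0.248         0.248  0.504  1.000

off-boundary cells scored: 232
affinity class agreement (median-rate mode): 85.8%
epitope class agreement: 100.0%
```

Most droplets hold no cell (Poisson occupancy 0.25); droplets whose trace
never shows an interior maximum within the hour cannot be quantified and are
excluded, which preferentially removes weak binders and slow secretors —
the processed heat map is dominated by high-affinity cells, as in real
screens. Epitope classes (from *y*<sub>max</sub>) recover exactly; affinity
classes estimated with the cohort-median secretion rate agree with truth for
~86% of unambiguous cells, the loss being driven by the spread of individual
secretion rates (a ±1 SD rate error moves the *K*<sub>D app</sub> estimate
by roughly a factor 2.5–3).

The other examples are one capability each: forward curves
(`01_relocation_curves.py`), calibration refitting (`02_calibration.py`),
the two-density ELISA chain (`04_elisa_beatty.py`, recovering known
affinities within a few percent), cohort arithmetic and t-tests
(`05_cohort_stats.py`), and image segmentation (`06_segmentation.py`).

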