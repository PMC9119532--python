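# ectolayers

Layer-resolved morphometrics of multiplex immunofluorescence images of
stratified squamous epithelium, built for studies of the ectocervical
mucosa — e.g. comparing women using the injectable contraceptive DMPA
(depot medroxyprogesterone acetate) with non-users of hormonal
contraception. The package turns calibrated multi-channel tissue scans plus
manually annotated apical/basal borders into per-sample barrier-integrity
metrics and runs the accompanying nonparametric group-comparison battery.

## What it computes

Every pixel of the epithelium gets a **relative depth**

    d(p) = D_a(p) / (D_a(p) + D_b(p)) ∈ [0, 1]

from its Euclidean distances `D_a`, `D_b` to the apical and basal border
polylines. Staining profiles over 50 depth bins then drive two
segmentations:

* **Four layers from the E-cadherin junction mesh** — superficial (no
  mesh), upper intermediate (fragmented "broken net"), lower intermediate
  (closed "intact net"), and parabasal (high nucleus density). Boundary
  rules: net area-fraction ≥ 0.05, mesh-cell closure ≥ 0.5 × profile
  maximum, nucleus density ≥ 2 × median, each sustained for two
  consecutive bins.
* **Three layers from a junction-protein mid-band** (desmoglein-1 or
  claudin-1) — marker-negative upper and lower layers flanking the
  contiguous band of Otsu-positive bins (area fraction ≥ 0.25).

Per-sample metrics: total and per-layer thickness (μm, mean over normal
probes from the apical border), E-cadherin area coverage (%), per-layer
MFI (AU), marker-band relative heights (%), band MFI and MFI/μm², CD4⁺
area fraction (%, the proxy for cell frequency), CD4⁺ per-layer
proportions and mean distance to the apical border (μm).

Cohort statistics: Mann–Whitney U per metric with joint Benjamini–Hochberg
FDR adjustment, plus exact contingency tests (Fisher 2×2 and
Freeman–Halton 2×k by full-margin enumeration), Pearson chi-squared with
Yates correction for 2×2, and Spearman correlation with an exact
permutation p at n ≤ 10.

Because no public image set accompanies this kind of study, the package
ships a first-class **synthetic scene generator** (`ectolayers.synthgen`)
that renders band-shaped epithelium with a seeded Voronoi junction mesh,
nucleus and CD4 spot placement, marker mid-bands, and Gaussian + Poisson
noise — together with the exact ground truth, so the whole pipeline is
testable end to end.

## Worked example

```python
from ectolayers import synthgen, pipeline

params = synthgen.scenario_params("dmpa_like", seed=11)
image, borders, truth = synthgen.generate_scene(params)
records, qc = pipeline.run_sample(image, borders)
for r in records:
    if r.metric_name.startswith("thickness"):
        print(f"{r.metric_name:28s} {r.value:7.1f} {r.units}")
```

prints (seed 11):

```
thickness_lower_im_um          106.9 um
thickness_parabasal_um          65.3 um
thickness_superficial_um        35.6 um
thickness_total_um             297.0 um
thickness_upper_im_um           89.1 um
```

i.e. the analysis recovers the scenario's configured layer heights
(36 / 86 / 110 / 65 μm, total 297 μm) from the rendered image alone: a thin
superficial layer and a thick fragmented upper IM layer, the DMPA-like
morphology. The matching `control_like` scenario yields ≈ 69 μm superficial
and ≈ 71 μm upper IM out of 300 μm.

The same workflow runs from the shell:

```bash
ectolayers synth --scenario control_like --seed 7 --out scene7/
ectolayers run --config cohort.yaml        # metrics.csv, comparison.tsv, qc.json
ectolayers ctest --test fisher "1,31;5,59" # exact p for a 2x2 table
```

## Layout

```
src/ectolayers/
  imgio.py      TIFF / JSON / CSV readers-writers, core data types
  geometry.py   epithelium mask, depth field, heights, areas
  synthgen.py   synthetic scenes + ground truth (also: `ectolayers synth`)
  layers.py     four-layer and three-layer segmentation, layer metrics
  cellquant.py  CD4+ detection, frequencies, proportions, distances
  stats.py      Mann-Whitney/BH, Fisher & Freeman-Halton, chi2, Spearman
  pipeline.py   per-sample orchestration, cohort runs, QC
  cli.py        command-line entry points
docs/methods.md details of the model, parameters and design choices
```
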