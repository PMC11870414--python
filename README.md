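# imnpheno

Single-cell phenotyping and survival analysis for cultures of induced
motor neurons (iMN) generated by direct conversion of fibroblasts.

Directly converted cultures are heterogeneous: only a fraction of cells
become neurons (small, bright, round cell body with neurites), the rest
stay flat non-neuronal cells or die as condensed debris. Studying
disease phenotypes in such cultures — neurite morphology, TDP-43
mislocalization, mitochondrial membrane potential and trafficking,
bioenergetic fluxes, and single-cell survival — requires finding,
segmenting and classifying individual cells before any per-cell
statistic means anything. `imnpheno` implements that measurement chain
as a tested, reusable pipeline:

* **synthetic microscopy** with pixel-exact ground truth (multi-channel
  scenes, time-lapse movies with programmed death hazards, neurite
  movies with motile mitochondria, flux plates, biosensor traces), so
  every stage is verifiable by recovery without any downloads;
* **image analysis** — background subtraction, blob detection with
  size/roundness exclusion, enhanced-contrast (EQ) image construction,
  marker-controlled watershed single-cell segmentation, nucleus-to-cell
  pairing;
* **classification** of each cell as iMN / non-neuron / dead from
  interpretable morphology features, behind a pluggable interface that
  accepts learned models;
* **morphometry** — skeleton-based neurite length and branch counts,
  nuclear vs cytosolic TDP-43 intensity ratios;
* **mitochondria** — per-cell TMRM punctum segmentation (count, area,
  intensity), kymograph construction and per-mitochondrion motility
  (motile fraction, antero-/retrograde distances, speeds);
* **bioenergetics** — OCR/ECAR stage analysis (basal, ATP-linked,
  maximal, spare capacity) with settle windows, non-mitochondrial /
  non-glycolytic subtraction, QC discard and per-cell normalization;
  PercevalHR 490/405 nm phase ratios around injections;
* **survival** — nearest-neighbour tracking, censored lifelines
  (entry at first iMN classification, event at disappearance, censoring
  at the last imaging day), and survival statistics implemented from
  first principles: the Kaplan-Meier product-limit estimator
  S(t) = Π_{tᵢ≤t}(1 − dᵢ/nᵢ), pairwise logrank tests, and Cox
  proportional hazards fitted by Newton-Raphson on the Efron partial
  likelihood, with Wald CIs logHR ± 1.96·SE.

See `docs/methods.md` for the models, assumptions and parameter
conventions.

## Worked example

Render a default mixed culture (20 iMN, 20 non-neurons, 10 dead cells at
20x) and run the phenotyping chain:

```bash
$ imnpheno phenotype --outdir out/ph --seed 7
50 cells; transformation efficiency 0.400
```

All 50 cells were detected and classified; 40% carry neuronal
morphology, matching the generated 20/50. `out/ph/cells.csv` holds one
row per cell with its class, soma geometry, and — for iMN — neurite
length, branch count, TDP-43 cytosol/nucleus ratio and mitochondrial
metrics.

Run a two-group survival experiment (control hazard 0.03/day vs mutant
0.06/day, i.e. a true hazard ratio of 2, imaged D12–D46 every second
day):

```bash
$ imnpheno survival --outdir out/surv --seed 3
        covariate   log_hr       hr       se  ci_lower  ci_upper        p
mutant_vs_control 0.420829 1.523224 0.253866  -0.07674  0.918398 0.097382
```

The pipeline detected and classified cells in every frame, linked them
into tracks (53 per group; tracks never classified iMN are excluded and
counted in QC), converted them to censored lifelines and fitted the Cox
model: the estimated hazard ratio for the mutant group is 1.52 with a
95% CI of exp(−0.077)–exp(0.918) ≈ 0.93–2.51, which covers the
programmed ratio of 2 — one seed at ~40 cells per group carries wide
intervals, which is exactly what the interval reports.
`out/surv/results.json` adds the Kaplan-Meier curves, the pairwise
logrank table and QC counts.

Other subcommands: `imnpheno simulate` (write synthetic data + ground
truth to disk), `imnpheno motility` (kymograph tracking of a neurite
movie), `imnpheno flux` (plate stage analysis from CSV or synthetic).
All take `--seed`, `--config` (YAML/JSON) and `--outdir`, and echo the
effective config for provenance.

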