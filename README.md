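# vffr

Noninvasive (virtual) fractional flow reserve from volumetric angiographic
images via 1D hemodynamic modelling, exercised end-to-end on synthetic
phantoms and cohorts.

The package covers the whole chain:

1. **Synthetic data** (`vffr.synthetic`) — Murray-law coronary trees,
   contrast-CT-like voxel phantoms (optionally with vein contamination,
   calcification blobs and voxel noise), and paired virtual/invasive FFR
   cohorts with a configurable noise model.
2. **Image → graph** (`vffr.imaging`) — preprocessing (slice dropping,
   morphological suppression of thin bright structures), threshold-band
   seeded segmentation, aorta separation and ostium detection, 3D
   skeletonization with distance-transform radii, and branch-graph
   construction with junction localisation.
3. **Vessel graphs** (`vffr.graph`) — typed data model, validation,
   stenosis editing (splitting the host segment so the narrowed extent is
   its own FFR-marked edge), vein pruning, and a versioned JSON schema.
4. **1D hemodynamics** (`vffr.hemo`) — unsteady mass/momentum equations on
   the tree with a linear elastic tube law (MacCormack interior scheme,
   characteristic boundaries, Newton-coupled junctions with machine-precision
   mass balance, resistive terminal outlets), plus an independent steady
   Poiseuille-network oracle.
5. **Personalization & FFR** (`vffr.personalize`) — inflow waveform from
   SBP/DBP/HR, age-bracket wall speeds, Murray-distributed terminal
   resistances calibrated to a coronary fraction of cardiac output,
   hyperemia induction, per-site/per-vessel/per-patient FFR and the strict
   `FFR < 0.80` ischemia rule.
6. **Diagnostics** (`vffr.diagnostics`) — confusion tables with plain
   Wilson score intervals, rank-concordance ROC/AUC, Bland–Altman agreement
   and mid-rank Spearman correlation.

## CLI

`vffr` exposes the pipeline as subcommands (`-v`/`-vv` for logging; results
go to files, logs to stderr; everything is deterministic per seed):

```sh
vffr phantom  --seed 7 --out out/phantom            # voxel phantom + truth graph
vffr extract  --volume out/phantom/phantom.raw \
              --seeds out/phantom/seeds.json --out out/graph.json
vffr validate --graph out/graph.json
vffr simulate --graph out/graph.json --out out/solution
vffr ffr      --graph out/graph.json --out out/ffr.json --mode unsteady
vffr cohort   --seed 1 --n 31 --out out/cohort.csv
vffr report   --cohort out/cohort.csv --out out/report --plots
vffr run      --config configs/demo.yaml --out out/demo   # full demo chain
```

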