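# afstress

Virtual left-atrial cohorts, monodomain atrial-fibrillation (AF)
stress-test simulations, simulated pulmonary-vein isolation (PVI), and
machine-learning prediction of 1-year ablation outcome.

The pipeline mirrors a simulation-augmented outcome-prediction study:

1. **`afstress.cohort`** — synthetic virtual patients: left-atrial shell
   meshes (deformed ellipsoids with four PV ostia + mitral orifice),
   spatially correlated image-intensity-ratio (IIR) fibrosis fields with
   controllable burden, rule-based fiber-field variants, history
   covariates, and recurrence labels drawn from a logistic model with
   planted coefficients.
2. **`afstress.ep`** — monodomain reaction–diffusion solver on surface
   meshes (P1 FEM diffusion with mass lumping, anisotropic conductivity
   along fibers, two-variable phenomenological atrial cell model, numba
   inner loop), conduction-velocity calibration, IIR→conductivity rule,
   S1–S2 effective-refractory-period measurement.
3. **`afstress.substrate`** — the four fibrosis-type substrate variants
   (combination / conduction-only / interstitial / none) with
   interstitial fibrosis as decoupled (no-flux) edges.
4. **`afstress.protocols`** — AF initiation by seeding phase
   singularities (three map variants) and circumferential PVI lesion
   bands at a fixed geodesic distance from the PV junctions (two sizes),
   with a verified closed-band isolation contract.
5. **`afstress.metrics`** — Hilbert-transform phase maps, winding-number
   phase-singularity detection and statistics, dominant frequency (DF)
   with the sustained-AF rule (DF ≥ 4.7 Hz), and imaging area metrics
   (fibrosis thresholded at IIR > 1.22).
6. **`afstress.battery`** — the 11-setup stress-test grid (fibrosis type
   2–4, fiber maps 5–6, PVI size 7, initiation maps 8–9, ERP 10–11),
   15 s pre- / 2 s post-ablation epochs ("paper" profile; a "desk"
   profile shortens pre to 4 s), and patient-signature assembly.
7. **`afstress.classify`** — KNN / SVM / random-forest / logistic
   classifiers, each ± PCA (retaining 95% variance), stratified k-fold
   cross-validation on three nested feature sets (history ⊂
   imaging+history ⊂ simulation+imaging+history), selection by largest
   mean ROC AUC.

## CLI

```bash
afstress cohort-gen --n 20 --seed 1 --out runs/cohort --effect-apd -2.5
afstress run-battery --cohort-dir runs/cohort --out runs/battery.csv \
    --profile desk --setups 1,4,7
afstress extract-signatures --battery runs/battery.csv --out runs/signatures.csv
afstress classify --signatures runs/signatures.csv --folds 5 --out runs/report.json
```

Meshes export as legacy ASCII VTK (`--write-vtk`), Vm movies as HDF5
(`afstress.io`), signatures as CSV.

## Notes

- Everything is deterministic per seed (`numpy.random.SeedSequence`
  splitting); cohorts, substrates, and signatures are bit-reproducible.
- The default cell model is phenomenological (two variables) with
  per-vertex APD/excitability scalings; a detailed ionic model can be
  plugged in behind `CellModelParams`.
- Units: mm, ms, mV; conductivities are effective diffusion coefficients
  (mm²/ms); 1 mm/ms = 1 m/s.
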