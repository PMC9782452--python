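# fdgclamp

Quantification pipeline for combined [¹⁸F]FDG-PET and
hyperinsulinemic–euglycemic clamp studies of multi-organ insulin
sensitivity, with a synthetic two-group cohort simulator that makes every
stage testable without access to subject-level data.

The package is aimed at metabolic-imaging researchers who need the full
chain from raw study data to cohort statistics:

* **Tissue glucose uptake from tracer kinetics.** FDG is irreversibly
  trapped over a scan, so its kinetics linearize in the Patlak–Gjedde
  coordinates: for frames past an equilibration time t*,

      C_T(t)/C_p(t) = K_i · ∫₀ᵗ C_p(s)ds / C_p(t) + V,

  where the slope K_i = K₁k₃/(k₂+k₃) (min⁻¹) is the net influx constant.
  Tissues imaged with a single late/static acquisition use the fractional
  uptake rate FUR = C_T(T)/∫₀ᵀC_p, the late-time approximation of K_i.
  Either rate converts to glucose uptake per kg of tissue via the plasma
  glucose level G during the scan, a lumped constant LC (1.2 skeletal
  muscle, 1.0 liver, 1.14 adipose) and the tissue density ρ:

      GU [µmol·kg⁻¹·min⁻¹] = K_i · G[µmol/L] / (LC · ρ[kg/L]).

* **Hybrid input function.** C_p(t) is assembled from an image-derived
  left-ventricle curve (0 to 4.5 min) spliced to arterialized plasma
  samples (4.5 min onward), with linear interpolation, trapezoidal AUC
  and a mono-exponential tail for extrapolation to infinity.

* **Clamp indices.** The M value is the steady-state glucose infusion
  rate corrected for glucose-space and urinary losses; whole-body Rd
  comes from the tracer balance (plasma clearance of the injected dose);
  endogenous glucose production is the difference EGP = Rd − GIR.
  Matsuda-ISI and the IFCC→NGSP HbA1c conversion cover the screening
  variables, and FFA suppression indexes adipose insulin response.

* **Cohort statistics.** Two-group comparisons (Student/Welch t,
  rank-sum, χ²) with Benjamini–Hochberg FDR control, age adjustment of
  brain uptake to the sample-mean age, per-group correlations, and a
  voxelwise two-sample t map with FDR thresholding and 26-connected
  cluster labelling.

* **Synthetic cohorts.** A generator draws a low-risk (n=22) and a
  high-risk (n=19) group from truncated normals with published group
  means/SDs, back-solves per-tissue kinetic parameters so each subject's
  uptake targets are honored, and forward-simulates plasma curves,
  frame-binned TACs (with count-statistics noise), clamp records and
  small voxel maps.

## Worked example

```bash
python analysis/01_simulate_cohort.py
python analysis/02_quantify_subjects.py
python analysis/03_group_statistics.py
python analysis/04_voxelwise_map.py
```

The second step prints the recovered group structure (seed 11):

```
quantified 41 subjects -> results/subjects.csv
  LR: M =  55.7 umol/kg/min, muscle GU =  47.7, brain GU =  144.2 umol/kg/min, EGP = -2.27 umol/kg/min
  HR: M =  38.2 umol/kg/min, muscle GU =  33.7, brain GU =  160.1 umol/kg/min, EGP =  1.62 umol/kg/min
```

The high-risk group shows lower whole-body insulin sensitivity (M value)
and muscle glucose uptake but *higher* brain uptake — the pattern the
generator encodes.  Step 3 reports 18 of 29 group differences as
FDR-significant (M value t = −3.60, adjusted p = 2.3×10⁻³; VAT uptake
t = −4.28), and step 4 recovers the regional brain elevation planted in
the high-risk maps with Jaccard 1.00 against the ground-truth block.

The same operations are available programmatically
(`fdgclamp.simulate_cohort`, `fdgclamp.run_pipeline`, …) and through the
CLI (`fdgclamp simulate|input-fn|patlak|fur|gu|clamp|cohort|run-all`).

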