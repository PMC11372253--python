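# phantomforge

Design and in-silico validation toolkit for a fillable, 3D-printable
three-compartment brain phantom for PET.

Anthropomorphic phantoms with separately fillable gray-matter (GM),
white-matter (WM) and dorsal-striatum compartments let a PET site impose
*known* activity concentrations with realistic brain geometry — and then ask
whether the scanner plus its partial-volume-effect (PVE) correction software
actually recovers them. `phantomforge` implements the full digital side of
that workflow:

1. **synthetic anatomy** — seeded ellipsoid-based label volumes with the
   phantom's topology: a closed cortical GM rind around a WM core, four
   striatal bodies (caudate/putamen per side), deep-nuclei sub-labels and
   deliberately disconnected voxel islands;
2. **compartment construction** — sub-label merging (deep GM nuclei → GM,
   substantia nigra/red nucleus → WM, caudate+putamen → striatum,
   CSF/extracranial → background), reassignment of 3D-disconnected islands
   to the surrounding prevalent tissue, 5-mm-lumen cylindrical connectors
   unifying the striatum, 6-mm bilateral fill pipes per compartment, and
   nearest-neighbor supersampling to 0.75 mm print resolution;
3. **mesh export** — marching-cubes surfaces per compartment, noise-shell
   removal, watertightness/wall-thickness validation, binary STL output;
4. **fill planning** — compartment volumes, and the ¹⁸F doses that realize
   target concentration ratios (GM/WM 2.80, striatum/WM 2.63 by default) at
   scan time, with half-life decay correction (T½ = 109.77 min);
5. **PET simulation** — piecewise-constant activity, isotropic Gaussian PSF
   (6.36 mm FWHM default), optional PET-grid resampling and Poisson noise;
6. **PVE correction** — Rousset's geometric transfer matrix (GTM),
   Müller-Gärtner in two WM-estimate variants, and Meltzer, plus a recovery
   harness that tabulates target vs uncorrected vs corrected concentrations.

## The statistics at the core

With a Gaussian PSF `h` and piecewise-constant true concentrations `c_j` on
region masks `M_j`, the observed image is `I = Σ_j c_j (M_j ⊗ h)`. The GTM
method builds `ω_ij = mean_{ROI_i}(M_j ⊗ h)` and solves `ω c = observed ROI
means`: exact for noiseless piecewise-constant activity, which is precisely
the phantom situation. Müller-Gärtner corrects GM voxelwise,
`(I − c_WM·(M_WM ⊗ h) − c_str·(M_str ⊗ h)) / (M_GM ⊗ h)`, and Meltzer divides
by the blurred whole-brain mask, correcting only tissue/background dilution.

## Worked example

```python
from phantomforge import *
from phantomforge.synthetic_anatomy import AnatomyParams
from phantomforge.fill_planner import compartment_volumes

anatomy = generate_anatomy(AnatomyParams(seed=1))     # 160³ source grid
model   = build_compartments(anatomy)                 # 0.75 mm print grid
volumes = compartment_volumes(model)                  # {GM: 209.4, WM: 502.4, striatum: 11.5} mL
plan    = plan_fill(volumes, wm_concentration_at_scan=16.01,
                    decay=DecayModel(injection_to_scan_min=30.0))
res     = evaluate_recovery(model, plan, PSFModel(6.36))
print(res.table.round(2))
```

prints

```
          target  uncorrected  rousset  meltzer  mg_cs  mg_ro
GM         44.83        31.23    44.83    39.73  44.80  44.83
WM         16.01        18.12    16.01    18.18  16.11  16.01
striatum   42.11        27.67    42.11    31.23  42.11  42.11
```

Reading the table: the planner programmed GM = 2.80 × WM = 44.83 kBq/mL and
striatum = 2.63 × WM = 42.11 kBq/mL. Uncorrected ROI means show the classic
PVE pattern — the thin GM rind and the small striatum lose counts to their
surroundings (31.23 < 44.83; 27.67 < 42.11) while the enclosed WM gains
spill-in from hotter GM (18.12 > 16.01). GTM and both Müller-Gärtner
variants recover the programmed values; Meltzer, which only undoes
brain/background dilution, lands characteristically in between. The
across-parcel GM standard deviation (`res.gm_parcel_sd`) drops from 0.15
uncorrected to ≈ 0 after GTM/MG — corrected GM is homogeneous, as it should
be for a uniformly filled compartment.

The same workflow is scriptable from a shell:

```bash
phantomforge synth --grid 160 --seed 1 -o anatomy.nii.gz
phantomforge build anatomy.nii.gz -o model.nii.gz
phantomforge mesh model.nii.gz --out-dir meshes/ --report report.json
phantomforge plan model.nii.gz --wm-kbq-ml 16.01 -o plan.json
phantomforge simulate model.nii.gz plan.json --fwhm 6.36 -o pet.nii.gz
phantomforge run -o results/          # everything end to end
```

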