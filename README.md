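# ichwm

**White-matter survival within and around an intracerebral hemorrhage,
quantified from diffusion tensor MRI.**

After an intracerebral hemorrhage (ICH), white matter is destroyed inside
the hematoma and disrupted around it — but how much survives, and whether
it recovers over the first month, is hard to measure without histology.
`ichwm` implements an MRI-only quantification for researchers studying
hemorrhagic stroke: from diffusion tensor imaging (DTI), it computes
fractional anisotropy (FA) maps and uses the volume of tissue with
**FA > 0.5** as a simple index of directional white matter, measured in
three compartments of a constant-radius analysis sphere centered on the
lesion — the hematoma itself, the perilesional zone, and a mirror-image
contralateral control sphere.

The headline quantity is the **perilesional white-matter deficit**: the
FA>0.5 volume expected in the perilesional zone if it matched the
contralateral WM fraction, minus the measured volume,

```
loss = perilesion_volume · (contra FA>0.5 / contra sphere volume)
       − (ipsi FA>0.5 − lesion FA>0.5)        [mL, positive = tissue lost]
```

Because patient images for such studies are typically not public, the
package includes a first-class synthetic cohort generator: ground-truthed
digital phantoms with anisotropic WM bundles, a low-FA hematoma core
(FA ≈ 0.15, as measured for clotting blood in vitro), a disrupted
perilesional shell, 32-direction b = 0–800 s/mm² Rician-noise DWI at
1×1×2.3 mm³, and a longitudinal day-3/14/30 design with realistic missing
timepoints. Every analysis stage is validated against the generator's
ground truth, and the statistics layer (paired t-tests, loss-vs-hematoma-
size regression, ANCOVA slope comparison, random-intercept mixed model with
Bonferroni-adjusted location contrasts) is calibrated by simulation.

## Worked example

`examples/03_roi_quantification.py` drives one noisy synthetic subject
(8 mL hematoma, shell attenuation 0.35) end to end:

```
segmented lesion: 7.93 mL (ground truth 7.99 mL)
sphere radius 22.0 mm, midline clearance 1.8 mm
    contralateral_sphere:   7.23 mL FA>0.5  (16.23 %)
      ipsilateral_sphere:   3.88 mL FA>0.5  ( 8.70 %)
                  lesion:   0.56 mL FA>0.5  ( 7.07 %)
              perilesion:   3.31 mL FA>0.5  ( 9.06 %)
perilesional loss: 2.63 mL (positive = white matter missing relative to the contralateral side)
```

Reading: the hematoma was segmented from the hypointense b=0 blob to within
1% of its true volume; the contralateral control sphere holds ≈ 16% white
matter while the perilesional zone holds only ≈ 9%, and scaling the
contralateral fraction to the perilesional volume says 2.6 mL of
directional white matter is missing around this lesion.

The other examples cover phantom construction (`01`), the tensor-fit round
trip (`02`, noiseless FA error ~1e-15), and a full longitudinal cohort with
mixed-model statistics (`04`). A thin CLI wraps the same stages:

```bash
ichwm run-all --config config.yaml      # simulate → fit → segment → quantify → stats
ichwm fit-dti --dwi s.nii.gz --bvec s.bvec --bval s.bval --out-prefix maps
ichwm cohort-stats --table cohort.csv --report out/
```

## Library layout

| module | contents |
|---|---|
| `ichwm.dti` | tensor fit (log-linear LS), eigen spectrum, FA / Westin / MD maps |
| `ichwm.phantom` | tensor-field phantoms, Rician DWI simulation, longitudinal evolution |
| `ichwm.cohort` | cohort designs, missingness patterns, table-level simulators |
| `ichwm.roi` | b=0 lesion segmentation, sphere placement, midline rule, mirroring |
| `ichwm.quantify` | FA>0.5 volumetry, perilesional deficit, longitudinal change |
| `ichwm.stats` | summaries, paired t, OLS, ANCOVA, mixed model, Bonferroni |
| `ichwm.pipeline` / `ichwm.cli` | end-to-end workflow, config, manifest, CLI |

See `docs/methods.md` for the model, parameter defaults and their
rationale, and what the synthetic cohorts do and do not demonstrate.

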