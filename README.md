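# thalcon

Thalamocortical resting-state functional connectivity analysis, built around
three ideas:

1. **Winner-take-all thalamus parcellation** — each thalamic voxel is
   labelled by the cortical ROI (prefrontal, motor, temporal, posterior
   parietal, somatosensory, occipital) whose mean BOLD series it correlates
   with most strongly, at the individual and at the group level (Fisher-z
   averaged correlation maps).
2. **Group inference on the Fisher-z scale** — ROI-to-ROI connectivity
   contrasts (patients vs controls, two-sample t), seed-to-voxel whole-brain
   z-maps with permutation cluster-level FWE correction (max-cluster-extent
   null), and behavioral correlations against motor-function scores
   including the change rate CR-MF = (FMA₁yr − FMA₀)/(FMA₁yr + FMA₀).
3. **A fully ground-truthed synthetic cohort generator** — a symmetric
   phantom with six cortical blocks and two thalami, latent band-limited
   (0.01–0.08 Hz) sources, planted voxel-to-cortex assignments, planted
   group connectivity deltas on the z scale, and planted clinical-score
   models, so every pipeline stage can be scored against known truth.

The preprocessing chain mirrors a standard resting-state protocol on
already-normalized data: discard 5 volumes → motion QC (exclude > 3 mm
translation) → linear detrend → zero-phase Butterworth band-pass
(0.01–0.08 Hz) → nuisance regression (6 motion parameters + WM + CSF; no
global signal regression, no smoothing). Left-lesion patients are flipped
about the mid-sagittal plane so all lesions sit in the right hemisphere, and
controls are duplicated with flipped copies (32 → 64 entries).

## Layout

| module | contents |
| --- | --- |
| `thalcon.core_io` | NIfTI / manifest / ROI-grouping I/O, grid validation |
| `thalcon.synthetic_cohort` | phantom anatomy, subject/cohort simulation, ground truth |
| `thalcon.signal_clean` | denoising chain + motion QC |
| `thalcon.hemisphere_align` | mid-sagittal flipping, cohort harmonization |
| `thalcon.wta_parcellation` | voxel-cortex correlations, winner-take-all maps |
| `thalcon.connectivity` | Fisher z, ROI-pair table, seed-to-voxel maps |
| `thalcon.group_inference` | t tests, permutation cluster FWE, behavior, demographics |
| `thalcon.pipeline` / `thalcon.cli` | staged orchestration + `thalcon` CLI |

## CLI

```bash
# write a synthetic study (BOLD + motion + confounds + manifest + truth)
thalcon simulate --out scratch/ds --seed 1

# run the full analysis from one YAML config
thalcon run --config config.yaml
thalcon report --config config.yaml

# or stage by stage (same outputs, byte-identical summary)
thalcon clean --config config.yaml
thalcon parcellate --config config.yaml
thalcon connect --config config.yaml
thalcon infer --config config.yaml
```

Minimal `config.yaml`:

```yaml
manifest: scratch/ds/manifest.tsv
atlas: scratch/ds/atlas.nii
grouping: scratch/ds/grouping.yaml
out_dir: scratch/out
n_perm: 500
seed: 7
```

Outputs land in `out_dir`: QC table, cleaned volumes, winner-take-all label
and agreement maps per thalamus, the per-entry connectivity table, the 12
ROI-pair contrasts, cluster tables for every significant seed, behavioral
correlations, the demographics table, and a timestamp-free `summary.json`
that is byte-identical across reruns with the same config and seed.

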