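# nprm — nonparametric residue mapping of dynamic PET kinetics

Voxel-level kinetic mapping for dynamic PET: each voxel time course is fit
as a nonnegative combination of data-derived basis residues (with a delay
grid search), kinetic parameters are read off the fitted Meier–Zierler
residue, and patient-specific uncertainties come from an image-domain
bootstrap built on the fit residuals.  A two-tissue-compartment reference
model and a synthetic 4-D phantom generator are included.

## Layout

| module | contents |
| --- | --- |
| `nprm.frames` | frame schedules, decay/duration fit weights, input functions, frame averaging |
| `nprm.residue` | residue objects, vascular/in-distribution/extracted decomposition, kinetic parameters (V_b, V_d, K_d, K_i, MTT, Ext), derived variables (MR, DV, BF) |
| `nprm.basis` | TAC segmentation, constrained residue fitting (NNLS over decrements), cross-validated basis-size selection |
| `nprm.fit` | voxel/VOI nonnegative least-squares fits, kinetic maps |
| `nprm.comp2c` | two-compartment model: forward curve, multistart fit, extended residue |
| `nprm.bootstrap` | residual-based data-generation process, replicate images, SE maps, MIP SEs, diagnostics |
| `nprm.summaries` | VOI aggregation, WRSS comparisons, paired Wilcoxon, log-linear SE regression, delay maps |
| `nprm.phantom` | synthetic phantoms (bolus input, known residues, factored skewed noise) |
| `nprm.io`, `nprm.cli` | NIfTI/CSV/JSON readers and writers, `nprm` command line |

## Command line

An end-to-end run on a synthetic phantom:

```sh
nprm simulate --preset mixed --seed 7 --dims 16,16,24 --sigma 0.3 --out work/sim
nprm build-basis --image work/sim/dyn.nii.gz --schedule work/sim/frames.csv \
    --aif work/sim/aif.csv --mask work/sim/mask.nii.gz --out work/basis.json
nprm fit --image work/sim/dyn.nii.gz --schedule work/sim/frames.csv \
    --aif work/sim/aif.csv --mask work/sim/mask.nii.gz \
    --basis work/basis.json --out work/maps
nprm bootstrap --image work/sim/dyn.nii.gz --schedule work/sim/frames.csv \
    --aif work/sim/aif.csv --mask work/sim/mask.nii.gz \
    --basis work/basis.json --nb 25 --seed 17 --out work/se
nprm summarize --maps work/maps --vois work/sim/organs.nii.gz --out work/voi.csv
nprm fit-2c --tac work/tacs.csv --schedule work/sim/frames.csv \
    --aif work/sim/aif.csv --out work/params2c.csv
```

Each output directory carries a `manifest.json` with settings and seeds;
parameter maps are one NIfTI per parameter with a JSON units sidecar.

## Conventions

Times are seconds; flow-like quantities are per minute (integrals convert
internally).  Activity is decay-corrected kBq/mL.  The vascular transit
threshold t* defaults to 15 s; frame fit weights default to
duration/decay-multiplier.  All stochastic steps take explicit seeds and
are bit-reproducible.
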