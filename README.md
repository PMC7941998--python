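# atriashape

Atlas-based left-atrial shape differentiation and deformation-field
radiomics for predicting atrial-fibrillation recurrence after catheter
ablation.

## What it does

Given a cohort of binary left-atrium segmentation masks with recurrence
labels and a clinical covariate table, the pipeline:

1. aligns the cohort to a template atrium (similarity registration by
   default, so pose and overall size are removed while shape is kept);
2. runs a voxelwise permutation **maxT** test on signed-distance values in
   a ±5 mm band around the template surface, with exact familywise error
   control, and projects the significant voxels onto the template surface
   as a **surface of interest (SOI)** — the remaining surface is the
   complement (cSOI);
3. registers the template non-rigidly (affine + cubic B-spline free-form
   deformation) to every patient and summarizes the displacement field
   over the SOI and cSOI: norm statistics, mean displacement components,
   and curl-component statistics — 16 descriptors per region, 32 per
   patient;
4. screens features with Wilcoxon rank-sum tests, trains gradient-boosted
   trees under repeated stratified 5-fold cross-validation with per-patient
   probability averaging, and compares shape / clinical / combined models
   by AUC with DeLong's test.

A synthetic cohort generator plants a known cap-shaped deformation on the
recurrence group (and draws clinical covariates matching published group
summaries), so the whole chain — alignment, statistics, SOI recovery,
features, model calibration — is validated against ground truth. See
[docs/methods.md](docs/methods.md) for the model and parameter rationale.

## Command-line usage

The `atriashape` command chains four stages (`simulate`, `soi`,
`features`, `evaluate`, or `all`), each writing a directory of artifacts
plus a manifest with the config hash. Exit codes: 0 success, 2
configuration error, 3 stage failure (e.g. an empty SOI cannot produce
features).

A small smoke-scale run (6+6 members, 3 mm grid, strong 8 mm planted
effect; finishes in ~20 s):

```python
# make_config.py
import dataclasses
from atriashape.config import RunConfig, save_config

cfg = RunConfig().with_seed(11)
cfg.spacing_mm = 3.0
cfg.synthetic = dataclasses.replace(
    cfg.synthetic, n_pos=6, n_neg=6, spacing_mm=3.0,
    effect_mm=8.0, variability_mm=0.5, seed=11,
)
cfg.stats.n_perm = 100
cfg.model.runs = 2
cfg.model.folds = 2
save_config(cfg, "config.yaml")
```

```text
$ atriashape all --config config.yaml --out run
INFO atriashape: simulate: config hash 7b562db76105bb07...
INFO atriashape: soi: config hash 7b562db76105bb07...
INFO atriashape: features: config hash 7b562db76105bb07...
INFO atriashape: evaluate: config hash 7b562db76105bb07...

$ python -m json.tool run/soi/soi.json | head -8
{
    "alpha": 0.05,
    "n_perm": 100,
    "exhaustive": false,
    "template_id": "member_008",
    "template_index": 8,
    "n_soi": 103,
    "n_csoi": 1237,

$ python -m json.tool run/evaluate/summary.json
{
    "auc": {
        "shape": 0.4,
        "csoi": 0.4,
        "clinical": 0.4,
        "combined": 0.4
    },
    "selected_shape_features": [
        "soi_norm_mean",
        "soi_norm_max",
        ...
    ],
    "compare_auc_combined_vs_clinical_p": 1.0
}
```

The SOI is found reliably even at this scale, but AUCs on 11 evaluable
patients with 2×2-fold CV are noise — this run demonstrates the plumbing,
not the model. Calibrated numbers come from the defaults (see below).
Artifacts include NIfTI masks and statistic maps, the template mesh as PLY
and as VTK polydata with per-vertex t / p / SOI channels, wide and long
feature tables, per-model reports and ROC curves. Re-running with the same
config and seed reproduces every artifact bit-for-bit.

## Library usage

Every stage is a plain function. The core loop, minus the CLI:

```python
import numpy as np
from atriashape import (
    CohortSpec, generate_cohort, select_template, build_atlas,
    signed_distance, narrow_band, permutation_maxT,
    extract_surface_mesh, identify_soi, compute_feature_table,
    wilcoxon_select, repeated_stratified_cv,
)

masks, labels, truth = generate_cohort(CohortSpec(n_pos=30, n_neg=30,
                                                  spacing_mm=2.0, seed=5))
neg = np.flatnonzero(labels == 0)
tpl = int(neg[select_template([masks[i] for i in neg])])
atlas = build_atlas(masks, labels, tpl, mode="similarity")

template = atlas.members[atlas.template_index]
region = narrow_band(signed_distance(template), 5.0)
stat = permutation_maxT([signed_distance(m) for m in atlas.members],
                        atlas.labels, n_perm=1000, seed=5, region=region)
mesh = extract_surface_mesh(template)
soi = identify_soi(stat, mesh, alpha=0.05, band_mm=3.0)

keep = [i for i in range(len(masks)) if i != tpl]
table, failures = compute_feature_table(template, [masks[i] for i in keep],
                                        soi, mesh, patient_ids=keep)
y = labels[keep]
selected, _ = wilcoxon_select(table.filter(like="soi_"), y, alpha=0.05)
report = repeated_stratified_cv(table[selected].to_numpy(), y,
                                runs=25, folds=5, seed=5)
print(report.auc)
```

On this planted 30+30 cohort the shape model reaches cross-validated
AUC ≈ 0.93, while label-shuffled nulls average ≈ 0.43–0.5.

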