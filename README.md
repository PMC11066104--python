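# relmap3d

Explainable 3D image classification toolkit: a scaled-down fully convolutional
3D classifier with composite Layerwise Relevance Propagation (LRP)
explanations, a quantitative validation battery for the resulting relevance
maps, and longitudinal cohort utilities — all exercisable end-to-end on
synthetic ellipsoidal "brain" phantoms with known lesion geometry, so nothing
requires external imaging data.

## What is in here

| Module | Purpose |
| --- | --- |
| `relmap3d.phantoms` | Synthetic fixtures: lesioned phantom cohorts, integer-labelled region atlases, reference maps, longitudinal visit tables. |
| `relmap3d.model` | NumPy implementation of the VGG-like 3D conv stack (conv / batch-norm / ReLU / average-pool / global-pool / dense-sigmoid), SGD training with stratified subject-disjoint cross-validation, sigmoid stripping, and exact batch-norm-into-conv fusion. |
| `relmap3d.lrp` | Composite LRP engine: generic/ε/αβ/flat rules per layer, whole-model explanation seeded at the logit, fold ensembling. |
| `relmap3d.postprocess` | clip → brain-mask → box-smooth → display normalization. |
| `relmap3d.validation` | Null pipelines (scrambled images, random weights, alternative task), averaged true-positive maps, percentile binarization + Dice curves, normalized cross-correlation, region aggregation, iterative occlusion with AOPC. |
| `relmap3d.matching` | Visit-history enumeration, pair costs, globally optimal Hungarian matching of progressive vs non-progressive subjects. |
| `relmap3d.progression` | Progression targets at yearly horizons, PCA compression of maps, nested-CV l1-logistic model suite (covariates / +prediction / +components), morphological records. |

The CNN stack is implemented directly on NumPy (no deep-learning framework is
required): the LRP engine needs direct access to every linear map, and the
test suite verifies the engine against an independent brute-force
implementation that materializes explicit contribution matrices.

Note one deliberate fidelity choice: the Dice coefficient defaults to the form
`|A∩B| / (|A|+|B|)` (identical maps score 0.5); pass `conventional=True` (or
`--dice-conventional` on the CLI) for the standard `2|A∩B| / (|A|+|B|)`.

## CLI

```bash
relmap3d synth cohort --n 50 --grid 48 --effect 0.3 --seed 1 --out cohort/
relmap3d synth atlas  --grid 48 --n-regions 8 --out atlas.nii.gz
relmap3d synth visits --n 200 --seed 1 --out visits.tsv
relmap3d train --cohort cohort/ --folds 5 --epochs 20 --seed 1 --out model/
relmap3d explain --volume cohort/sub-0000.nii.gz --rules composite --out R.nii.gz
relmap3d postprocess --map R.nii.gz --volume cohort/sub-0000.nii.gz --smooth 3 --out R_pp.nii.gz
relmap3d validate --maps maps/ --reference G.nii.gz --atlas atlas.nii.gz --out report/
relmap3d match --visits visits.tsv --out pairs.tsv
```

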