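"""Shared end-to-end phantom experiment used by the acceptance checks.

One desk-scale configuration: a cubic phantom cohort with a planted lesion
region (and a sex-linked region for the alternative-task null pipeline), a
cross-validated scaled classifier, out-of-sample composite relevance maps,
and the derived localization / occlusion / overlap measurements.
"""

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from relmap3d import lrp, phantoms, postprocess, validation
from relmap3d.model import build_model, fuse_batchnorm, strip_sigmoid, train_classifier

GRID = 20
BLOCKS = 3
BASE_CHANNELS = 8
N_REGIONS = 32
LESION_REGIONS = (5,)
SEX_REGIONS = (9,)
EFFECT = 0.75
SEX_EFFECT = 0.5
NOISE_SD = 0.05
JITTER = 0.15
N_PER_CLASS = 100
FOLDS = 5
EPOCHS = 30
LR = 0.05
WEIGHT_DECAY = 1e-3
AUGMENT_WIDTH = 3
AUGMENT_PROB = 0.5
AUGMENT_MAX_BOXES = 6
RESTARTS = 2
OCCLUSION_CUBE = 3
OCCLUSION_ITERS = 3
SEX_EPOCHS = 20
REFERENCE_BLUR = 0.3


@dataclass
class PhantomExperiment:
    atlas: object
    cohort: list
    train_result: object
    fused: list
    auc: float
    lesion_mask: np.ndarray
    lesion_fraction: float
    true_positives: list
    task_maps: dict
    concentration: float
    reference_map: np.ndarray = None
    sex_model: object = None
    sex_auc: float = None
    sex_auc_on_lesion: float = None


def run_phantom_experiment(seed: int = 1, with_sex_model: bool = False,
                           n_per_class: int = N_PER_CLASS,
                           epochs: int = EPOCHS) -> PhantomExperiment:
    atlas = phantoms.build_atlas(GRID, n_regions=N_REGIONS, seed=0)
    cohort = phantoms.generate_cohort(
        n_per_class, grid=GRID, atlas=atlas,
        lesion_spec=phantoms.LesionSpec(regions=LESION_REGIONS, effect=EFFECT),
        noise_sd=NOISE_SD, seed=seed + 10, intensity_jitter=JITTER,
        sex_regions=SEX_REGIONS, sex_effect=SEX_EFFECT,
    )
    proto = build_model(grid=GRID, blocks=BLOCKS, base_channels=BASE_CHANNELS,
                        seed=seed)
    result = train_classifier(
        proto, cohort, folds=FOLDS, epochs=epochs, batch=8, lr=LR, seed=seed,
        weight_decay=WEIGHT_DECAY, augment=True, augment_width=AUGMENT_WIDTH,
        augment_prob=AUGMENT_PROB, augment_max_boxes=AUGMENT_MAX_BOXES,
        restarts=RESTARTS,
    )
    auc = roc_auc_score(result.predictions.label, result.predictions.yhat)
    fused = [fuse_batchnorm(strip_sigmoid(m)) for m in result.fold_models]

    brain = phantoms.brain_mask(GRID)
    lesion_mask = atlas.region_mask(LESION_REGIONS) & brain
    lesion_fraction = lesion_mask.sum() / brain.sum()

    pred = dict(zip(result.predictions.subject_id, result.predictions.yhat))
    folds = result.fold_assignment
    tps = [p for p in cohort if p.label == 1 and pred[p.subject_id] > 0.5]
    task_maps = {}
    fracs = []
    for p in tps:
        m = fused[folds[p.subject_id]]
        raw = lrp.explain(m, p.volume, input_id=p.subject_id).map
        pp = postprocess.postprocess(raw, p.volume)
        task_maps[p.subject_id] = pp
        total = pp.data.sum()
        fracs.append(pp.data[lesion_mask].sum() / total if total > 0 else 0.0)
    concentration = float(np.mean(fracs)) if fracs else 0.0

    exp = PhantomExperiment(
        atlas=atlas, cohort=cohort, train_result=result, fused=fused, auc=auc,
        lesion_mask=lesion_mask, lesion_fraction=float(lesion_fraction),
        true_positives=tps, task_maps=task_maps, concentration=concentration,
    )
    exp.reference_map = phantoms.generate_reference_map(atlas, LESION_REGIONS,
                                                        blur=REFERENCE_BLUR)
    if with_sex_model:
        _attach_sex_model(exp, seed)
    return exp


def _attach_sex_model(exp: PhantomExperiment, seed: int):
    sexco = [
        phantoms.Phantom(volume=p.volume, label=1 if p.sex == "F" else 0,
                         lesion_mask=p.lesion_mask, subject_id=p.subject_id,
                         site=p.site, age=p.age, sex=p.sex)
        for p in exp.cohort
    ]
    proto = build_model(grid=GRID, blocks=BLOCKS, base_channels=BASE_CHANNELS,
                        seed=seed + 500)
    res = train_classifier(proto, sexco, folds=2, epochs=SEX_EPOCHS, batch=8, lr=LR,
                           seed=seed + 500, weight_decay=WEIGHT_DECAY,
                           augment=True, augment_width=AUGMENT_WIDTH,
                           augment_prob=AUGMENT_PROB,
                           augment_max_boxes=AUGMENT_MAX_BOXES,
                           restarts=RESTARTS)
    exp.sex_auc = float(roc_auc_score(res.predictions.label, res.predictions.yhat))
    meta = pd.DataFrame([p.metadata() for p in exp.cohort])
    merged = res.predictions.merge(meta, on="subject_id", suffixes=("_sex", ""))
    exp.sex_auc_on_lesion = float(roc_auc_score(merged.label, merged.yhat))
    exp.sex_model = fuse_batchnorm(strip_sigmoid(res.fold_models[0]))


def null_postprocessed_maps(exp: PhantomExperiment, kind: str, seed: int = 0,
                            subjects=None) -> dict:
    """Postprocessed null-pipeline maps keyed by subject id."""
    subjects = subjects if subjects is not None else exp.true_positives
    folds = exp.train_result.fold_assignment
    rng = np.random.default_rng(seed)
    out = {}
    if kind == "random_weights":
        vols = np.stack([p.volume for p in subjects])
        maps = validation.null_pipeline_maps("random_weights", exp.fused[0], vols,
                                             seed=seed)
        for p, m in zip(subjects, maps):
            out[p.subject_id] = postprocess.postprocess(m, p.volume)
    elif kind == "random_images":
        # per-subject out-of-fold model explains the subject's scrambled input
        for p in subjects:
            m = exp.fused[folds[p.subject_id]]
            sv = validation.scrambled_volume(p.volume, rng)
            raw = lrp.explain(m, sv).map
            out[p.subject_id] = postprocess.postprocess(raw, p.volume)
    elif kind == "alt_task":
        if exp.sex_model is None:
            raise ValueError("experiment was run without the sex model")
        for p in subjects:
            raw = lrp.explain(exp.sex_model, p.volume).map
            out[p.subject_id] = postprocess.postprocess(raw, p.volume)
    else:
        raise ValueError(kind)
    return out


def mean_aopc(exp: PhantomExperiment, maps_by_subject: dict, subjects=None,
              iterations: int = OCCLUSION_ITERS, cube: int = OCCLUSION_CUBE,
              seed: int = 0) -> float:
    subjects = subjects if subjects is not None else exp.true_positives
    folds = exp.train_result.fold_assignment
    vals = []
    for i, p in enumerate(subjects):
        model = exp.train_result.fold_models[folds[p.subject_id]]
        # independent noise realization per participant
        tr = validation.occlusion_trace(model, p.volume,
                                        maps_by_subject[p.subject_id],
                                        iterations=iterations, cube=cube,
                                        seed=seed + 997 * i)
        vals.append(tr.aopc)
    return float(np.mean(vals))


def average_map(maps_by_subject: dict) -> lrp.RelevanceMap:
    ids = sorted(maps_by_subject)
    return validation.average_true_positive_map(
        [maps_by_subject[i] for i in ids], np.ones(len(ids)), np.ones(len(ids)))
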