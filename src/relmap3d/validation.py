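"""Quantitative validation battery for relevance maps.

Null pipelines (scrambled inputs, random weights, alternative task), averaged
true-positive maps, percentile binarization with Dice curves, normalized
cross-correlation, region-wise aggregation, and the iterative occlusion test
with its area over the perturbation curve (AOPC).

Note the Dice coefficient is implemented in the printed form
``|A∩B| / (|A| + |B|)`` (identical maps score 0.5); pass ``conventional=True``
for the standard ``2|A∩B| / (|A| + |B|)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lrp import RelevanceMap, explain
from .model import ClassifierModel, build_model
from .phantoms import SyntheticAtlas

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# null pipelines


def scrambled_volume(volume: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Scramble one input: i.i.d. N(mean(X), sd(X)) noise, clipped at 0.

    The mean and spread are the scalar statistics of the input volume itself,
    so the draw keeps the image's intensity distribution but destroys all of
    its spatial structure — no anatomical or class information survives.
    """
    v = np.asarray(volume, dtype=float)
    if v.ndim == 4:  # a stack: scramble against the pooled scalar statistics
        v = v.reshape(-1)
    return np.clip(rng.normal(float(v.mean()), float(v.std()),
                              size=np.asarray(volume, dtype=float).shape[-3:]),
                   0.0, None)


def null_pipeline_maps(
    kind: str,
    model: ClassifierModel,
    volumes,
    seed: int = 0,
    alt_model: ClassifierModel | None = None,
    rules="composite",
) -> list[RelevanceMap]:
    """Relevance maps from one of the sanity-check null pipelines.

    kind="random_images": the task model explains voxel-wise Gaussian noise
    images with the cohort's mean and SD.  kind="random_weights": an untrained
    model of the same architecture explains the real volumes.  kind="alt_task":
    ``alt_model`` (a classifier for an attribute orthogonal to the task label)
    explains the real volumes.  Everything else in the LRP machinery is
    identical to the task pipeline.
    """
    vols = np.asarray(volumes, dtype=float)
    rng = np.random.default_rng(seed)
    if kind == "random_images":
        inputs = [scrambled_volume(v, rng) for v in vols]
        m = model
    elif kind == "random_weights":
        cfg = {k: v for k, v in model.config.items() if k != "seed"}
        m = build_model(**cfg, seed=seed + 7919)
        from .model import fuse_batchnorm, strip_sigmoid

        m = fuse_batchnorm(strip_sigmoid(m))
        inputs = list(vols)
    elif kind == "alt_task":
        if alt_model is None:
            raise ValueError("alt_task pipeline requires alt_model")
        m = alt_model
        inputs = list(vols)
    else:
        raise ValueError(f"unknown null pipeline kind {kind!r}")
    return [explain(m, v, rules=rules).map for v in inputs]


# ---------------------------------------------------------------------------
# averaged maps and overlap metrics


def average_true_positive_map(maps, predictions, labels) -> RelevanceMap:
    """Voxel-wise mean over maps with label 1 and yhat > 0.5."""
    preds = np.asarray(predictions, dtype=float)
    labs = np.asarray(labels, dtype=int)
    sel = (labs == 1) & (preds > 0.5)
    if not sel.any():
        raise ValueError("no true positives (label 1 with yhat > 0.5)")
    arrs = [m.data if isinstance(m, RelevanceMap) else np.asarray(m)
            for m, keep in zip(maps, sel) if keep]
    return RelevanceMap(np.mean(arrs, axis=0), {"n_true_positives": int(sel.sum())})


def binarize_percentile(m, p: float) -> np.ndarray:
    """voxel = 1 iff value > percentile(map, p); strict inequality."""
    if not 0 <= p < 100:
        raise ValueError(f"percentile must be in [0, 100), got {p}")
    data = m.data if isinstance(m, RelevanceMap) else np.asarray(m, dtype=float)
    thr = np.percentile(data, p)
    return (data > thr).astype(np.uint8)


def dice(a_bin, b_bin, conventional: bool = False) -> float:
    """Sørensen-Dice as printed: Σ r·g / (Σ r + Σ g); factor 2 only if asked."""
    a = np.asarray(a_bin)
    b = np.asarray(b_bin)
    if a.shape != b.shape:
        raise ValueError("binarized maps must share a grid")
    denom = float(a.sum() + b.sum())
    if denom == 0:
        logger.info("dice of two empty maps defined as 0")
        return 0.0
    inter = float((a * b).sum())
    return (2.0 * inter if conventional else inter) / denom


@dataclass
class DiceCurve:
    percentiles: np.ndarray
    values: np.ndarray
    label: str = ""

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"percentile": self.percentiles,
                             "sdc": self.values, "pipeline": self.label})


def dice_curve(avg_map, reference, percentiles=None, label: str = "",
               conventional: bool = False) -> DiceCurve:
    """SDC at each percentile under symmetric thresholding of both maps."""
    if percentiles is None:
        percentiles = np.arange(100)
    ps = np.asarray(percentiles, dtype=float)
    vals = np.array([
        dice(binarize_percentile(avg_map, p), binarize_percentile(reference, p),
             conventional=conventional)
        for p in ps
    ])
    return DiceCurve(percentiles=ps, values=vals, label=label)


def ncc(a, b) -> float:
    """Normalized cross-correlation (Pearson over voxels)."""
    x = (a.data if isinstance(a, RelevanceMap) else np.asarray(a, dtype=float)).ravel()
    y = (b.data if isinstance(b, RelevanceMap) else np.asarray(b, dtype=float)).ravel()
    if x.shape != y.shape:
        raise ValueError("maps must share a grid")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum() * (yc**2).sum())
    if denom == 0:
        raise ValueError("ncc undefined for a constant map")
    return float((xc * yc).sum() / denom)


def region_aggregate(m, atlas: SyntheticAtlas, stat: str = "mean") -> pd.DataFrame:
    """Per-region aggregate of map values (mean, sum, or max)."""
    if stat not in ("mean", "sum", "max"):
        raise ValueError(f"stat must be mean|sum|max, got {stat!r}")
    data = m.data if isinstance(m, RelevanceMap) else np.asarray(m, dtype=float)
    if data.shape != atlas.labels.shape:
        raise ValueError("atlas grid does not match map grid")
    rows = []
    for rid in atlas.region_ids:
        vals = data[atlas.labels == rid]
        agg = {"mean": vals.mean, "sum": vals.sum, "max": vals.max}[stat]()
        rows.append({"region_id": rid, "region": atlas.names[rid],
                     "stat": stat, "value": float(agg)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# occlusion


@dataclass
class PerturbationTrace:
    """Predictions [ŷ₀, ŷ¹, …] from iterative occlusion plus the cube centers."""

    predictions: list[float]
    centers: list[tuple[int, int, int]] = field(default_factory=list)
    fallback_random: int = 0

    @property
    def aopc(self) -> float:
        return aopc(self.predictions)


def aopc(trace) -> float:
    """Mean of (ŷ₀ − ŷⁱ) over the perturbation iterations."""
    preds = trace.predictions if isinstance(trace, PerturbationTrace) else list(trace)
    if len(preds) < 2:
        raise ValueError("trace needs a baseline and at least one iteration")
    y0 = preds[0]
    return float(np.mean([y0 - y for y in preds[1:]]))


def occlusion_trace(
    model: ClassifierModel,
    volume: np.ndarray,
    relevance,
    iterations: int = 20,
    cube: int = 15,
    seed: int = 0,
) -> PerturbationTrace:
    """Iteratively occlude the most relevant cube and re-predict.

    Each iteration centers a ``cube``³ box of U(0,1) noise on the argmax voxel
    of the working relevance map (ties broken lexicographically, clipped at
    volume borders), re-runs the model on the sigmoid scale, and zeroes the
    cube in the working map so occlusion windows do not overlap.  If relevance
    is exhausted the remaining picks fall back to uniform-random brain voxels.
    """
    if cube % 2 == 0:
        raise ValueError(f"cube width must be odd, got {cube}")
    vol = np.asarray(volume, dtype=float).copy()
    rmap = (relevance.data if isinstance(relevance, RelevanceMap)
            else np.asarray(relevance, dtype=float)).copy()
    if rmap.shape != vol.shape:
        raise ValueError("relevance map not aligned with volume")
    rng = np.random.default_rng(seed)
    half = cube // 2
    brain = np.argwhere(vol > 0)

    preds = [float(model.predict(vol)[0])]
    centers: list[tuple[int, int, int]] = []
    fallback = 0
    for _ in range(iterations):
        if np.any(rmap > 0):
            center = np.unravel_index(int(np.argmax(rmap)), rmap.shape)
        else:
            fallback += 1
            center = tuple(brain[rng.integers(len(brain))])
            logger.info("relevance exhausted; falling back to random brain voxel")
        sl = tuple(
            slice(max(c - half, 0), min(c + half + 1, n))
            for c, n in zip(center, vol.shape)
        )
        shape = tuple(s.stop - s.start for s in sl)
        vol[sl] = rng.uniform(0.0, 1.0, size=shape)
        rmap[sl] = 0.0
        centers.append(tuple(int(c) for c in center))
        preds.append(float(model.predict(vol)[0]))
    return PerturbationTrace(predictions=preds, centers=centers,
                             fallback_random=fallback)
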