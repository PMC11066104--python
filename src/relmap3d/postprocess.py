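"""Raw relevance maps -> analysis-ready maps: clip, mask, smooth, normalize.

The documented pipeline order is clip -> mask -> smooth; clipping and masking
commute, smoothing and masking do not (smoothing is therefore an explicit,
separate stage rather than a universal default).
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage

from .lrp import RelevanceMap


def _as_map(m) -> tuple[np.ndarray, dict]:
    if isinstance(m, RelevanceMap):
        return m.data, dict(m.meta)
    return np.asarray(m, dtype=float), {}


def clip_positive(m):
    """Voxel-wise max(r, 0): keep only evidence for the positive class."""
    data, meta = _as_map(m)
    return RelevanceMap(np.maximum(data, 0.0), meta)


def mask_brain(m, volume):
    """Nullify relevance wherever the input volume is exactly zero."""
    data, meta = _as_map(m)
    vol = np.asarray(volume)
    if vol.shape != data.shape:
        raise ValueError(f"grid mismatch: map {data.shape} vs volume {vol.shape}")
    out = data.copy()
    out[vol == 0] = 0.0
    return RelevanceMap(out, meta)


def smooth_box(m, width: int = 3):
    """Convolve with a constant normalized width³ box kernel (zero-padded)."""
    if width % 2 == 0:
        raise ValueError(f"box width must be odd, got {width}")
    data, meta = _as_map(m)
    if width == 1:
        return RelevanceMap(data.copy(), meta)
    out = ndimage.uniform_filter(data, size=width, mode="constant", cval=0.0)
    return RelevanceMap(out, meta)


def normalize_display(m):
    """Affine rescale to [0, 1] for visualization; order preserving."""
    data, meta = _as_map(m)
    lo, hi = float(data.min()), float(data.max())
    if hi == lo:
        warnings.warn("constant map cannot be normalized; returning zeros",
                      stacklevel=2)
        return RelevanceMap(np.zeros_like(data), meta)
    return RelevanceMap((data - lo) / (hi - lo), meta)


def postprocess(m, volume, smooth: int | None = None):
    """clip -> mask -> (optional) smooth -> re-mask."""
    out = mask_brain(clip_positive(m), volume)
    if smooth is not None and smooth > 1:
        out = mask_brain(smooth_box(out, smooth), volume)
    return out
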