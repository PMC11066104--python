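"""Composite layerwise relevance propagation through the fused classifier.

Relevance is seeded at the single output unit with the logit and propagated
backwards layer by layer.  Every layer is one of a small set of linear maps
(convolution, dense, average pooling treated as fixed-weight convolution) or a
shape/activation pass-through (ReLU, flatten), and each linear layer is
assigned one of four propagation rules:

* ``generic`` — the original proportional-decomposition rule,
* ``epsilon`` — generic with a sign-stabilized ε added to the denominator,
* ``alphabeta`` — positive/negative contributions normalized separately and
  recombined with weights α and −β (α − β = 1 enforced),
* ``flat`` — each downstream neuron's relevance split uniformly over the
  upstream neurons actually connected to it (zero-padded border positions are
  excluded from the count unless ``flat_count_padding``).

The composite strategy used throughout: flat for the first convolution (and
hence the input), alphabeta for the remaining convolutions, epsilon for the
output layer, generic for the pooling maps, pass-through for activations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import (
    AvgPool3d,
    ClassifierModel,
    Conv3d,
    Dense,
    Flatten,
    GlobalAvgPool,
    sigmoid,
)

RULES = ("generic", "epsilon", "alphabeta", "flat", "pass")

_LINEAR = (Conv3d, Dense, AvgPool3d, GlobalAvgPool)


@dataclass
class RuleAssignment:
    """Per-layer propagation rule plus shared rule parameters."""

    layer_rules: list[str]
    epsilon: float = 1e-9
    alpha: float = 1.0
    beta: float = 0.0
    flat_count_padding: bool = False

    def __post_init__(self):
        for r in self.layer_rules:
            if r not in RULES:
                raise ValueError(f"unknown rule {r!r}")
        if not np.isclose(self.alpha - self.beta, 1.0):
            raise ValueError(f"alpha - beta must equal 1 (got {self.alpha - self.beta})")
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be >= 0")
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")


def composite_assignment(model: ClassifierModel, **params) -> RuleAssignment:
    """Flat on the first conv, alphabeta on later convs, epsilon on the output."""
    rules = []
    seen_conv = False
    for layer in model.layers:
        if isinstance(layer, Conv3d):
            rules.append("flat" if not seen_conv else "alphabeta")
            seen_conv = True
        elif isinstance(layer, Dense):
            rules.append("epsilon")
        elif isinstance(layer, (AvgPool3d, GlobalAvgPool)):
            rules.append("generic")
        else:
            rules.append("pass")
    return RuleAssignment(layer_rules=rules, **params)


def generic_assignment(model: ClassifierModel, **params) -> RuleAssignment:
    rules = [
        "generic" if isinstance(l, _LINEAR) else "pass" for l in model.layers
    ]
    return RuleAssignment(layer_rules=rules, **params)


@dataclass
class RelevanceMap:
    """Voxel relevances aligned with the input volume, plus provenance."""

    data: np.ndarray
    meta: dict = field(default_factory=dict)

    @property
    def shape(self):
        return self.data.shape

    def total(self) -> float:
        return float(self.data.sum())


@dataclass
class ExplainResult:
    map: RelevanceMap
    logit: float  # raw prediction on the unbounded scale
    yhat: float  # sigmoid-scale prediction in [0, 1]


# ---------------------------------------------------------------------------
# single-layer propagation rules


def _stabilize(z: np.ndarray, eps: float) -> np.ndarray:
    if eps == 0:
        return z
    return z + eps * np.where(z >= 0, 1.0, -1.0)


def _safe_div(r: np.ndarray, z: np.ndarray, absorbed: list | None = None):
    zero = z == 0
    if zero.any():
        if absorbed is not None:
            absorbed[0] += float(np.abs(r[zero]).sum())
        z = np.where(zero, 1.0, z)
        r = np.where(zero, 0.0, r)
    return r / z


def propagate_epsilon(layer, relevance, activations, epsilon=0.0, *,
                      with_bias=True, absorbed=None):
    """ε-stabilized proportional decomposition; ε=0 reduces to the generic rule."""
    b = layer.bias() if (with_bias and hasattr(layer, "bias")) else None
    z = layer.lin(activations, b=b)
    zs = _stabilize(z, epsilon)
    s = _safe_div(relevance, zs, absorbed)
    return activations * layer.lin_t(s)


def propagate_generic(layer, relevance, activations, *, with_bias=True):
    """Original proportional rule; rejects exact zero denominators."""
    b = layer.bias() if (with_bias and hasattr(layer, "bias")) else None
    z = layer.lin(activations, b=b)
    if np.any(z == 0):
        raise ZeroDivisionError(
            "zero denominator in generic relevance propagation; "
            "use propagate_epsilon with epsilon > 0"
        )
    return activations * layer.lin_t(relevance / z)


def propagate_alphabeta(layer, relevance, activations, alpha=1.0, beta=0.0, *,
                        with_bias=True, absorbed=None):
    """Sign-split rule: positive and negative contributions normalized apart.

    Contribution signs are those of the products a_m * w_mn, decomposed exactly
    via the four (a±, w±) cross terms; denominators that vanish have their term
    skipped (relevance absorbed).
    """
    if not np.isclose(alpha - beta, 1.0):
        raise ValueError("alpha - beta must equal 1")
    ap = np.maximum(activations, 0)
    an = np.minimum(activations, 0)
    if hasattr(layer, "weight_parts"):
        wp, wn = layer.weight_parts()
        bias = layer.bias() if with_bias else None
        bp = np.maximum(bias, 0) if bias is not None else None
        bn = np.minimum(bias, 0) if bias is not None else None
        zp = layer.lin(ap, w=wp, b=bp) + layer.lin(an, w=wn)
        zn = layer.lin(ap, w=wn, b=bn) + layer.lin(an, w=wp)
        out = np.zeros_like(activations, dtype=float)
        if alpha != 0:
            sp = _safe_div(relevance, zp, absorbed)
            out += alpha * (ap * layer.lin_t(sp, w=wp) + an * layer.lin_t(sp, w=wn))
        if beta != 0:
            sn = _safe_div(relevance, zn, absorbed)
            out -= beta * (ap * layer.lin_t(sn, w=wn) + an * layer.lin_t(sn, w=wp))
        return out
    # fixed nonnegative-weight linear map (pooling): products share a's sign
    zp = layer.lin(ap)
    zn = layer.lin(an)
    out = np.zeros_like(activations, dtype=float)
    if alpha != 0:
        out += alpha * ap * layer.lin_t(_safe_div(relevance, zp, absorbed))
    if beta != 0:
        out -= beta * an * layer.lin_t(_safe_div(relevance, zn, absorbed))
    return out


def propagate_flat(layer, relevance, activations, *, count_padding=False,
                   absorbed=None):
    """Uniform split: r(a_m) = Σ_n r(a_n) / |o_n| over connected neurons."""
    if not hasattr(layer, "ones_weights"):
        raise TypeError(f"flat rule needs an explicit-weight layer, got {layer.kind}")
    w1 = layer.ones_weights()
    if count_padding and isinstance(layer, Conv3d):
        counts_value = layer.in_c * layer.k**3
        z = np.full_like(layer.lin(activations, w=w1), float(counts_value))
    else:
        z = layer.lin(np.ones_like(activations), w=w1)
    s = _safe_div(relevance, z, absorbed)
    return layer.lin_t(s, w=w1)


# ---------------------------------------------------------------------------
# whole-model engine


def _check_explainable(model: ClassifierModel):
    if model.has_sigmoid:
        raise ValueError("model must be sigmoid-stripped (logit mode); "
                         "call strip_sigmoid first")
    if any(l.kind == "batchnorm" for l in model.layers):
        raise ValueError("model contains unfused batch-norm layers; "
                         "call fuse_batchnorm first")


def _propagate_layer(layer, rule, r, a, rules: RuleAssignment, absorbed):
    if rule == "pass":
        if isinstance(layer, Flatten):
            layer.lin(a)  # record shape
            return layer.lin_t(r)
        return r
    if rule == "generic":
        return propagate_epsilon(layer, r, a, epsilon=0.0, absorbed=absorbed)
    if rule == "epsilon":
        return propagate_epsilon(layer, r, a, epsilon=rules.epsilon, absorbed=absorbed)
    if rule == "alphabeta":
        return propagate_alphabeta(layer, r, a, alpha=rules.alpha, beta=rules.beta,
                                   absorbed=absorbed)
    if rule == "flat":
        return propagate_flat(layer, r, a, count_padding=rules.flat_count_padding,
                              absorbed=absorbed)
    raise ValueError(f"unknown rule {rule!r}")


def explain(
    model: ClassifierModel,
    volume: np.ndarray,
    rules: RuleAssignment | str = "composite",
    input_id: str | None = None,
) -> ExplainResult:
    """Produce the raw (pre-postprocessing) relevance map for one volume."""
    _check_explainable(model)
    if isinstance(rules, str):
        if rules == "composite":
            rules = composite_assignment(model)
        elif rules == "generic":
            rules = generic_assignment(model)
        else:
            raise ValueError(f"unknown rule strategy {rules!r}")
    if len(rules.layer_rules) != len(model.layers):
        raise ValueError("rule assignment does not match model layers")

    v = np.asarray(volume, dtype=np.float64)
    if v.ndim != 3:
        raise ValueError(f"expected a 3D volume, got ndim={v.ndim}")
    x = v[None, None]
    grid = model.config.get("grid")
    if grid is not None and v.shape != (grid,) * 3:
        raise ValueError(f"volume shape {v.shape} does not match model grid {grid}")

    acts = []
    h = x
    for layer in model.layers:
        acts.append(h)
        h = layer.forward(h, training=False)
    logit = float(h[0, 0])
    yhat = float(sigmoid(logit))

    absorbed = [0.0]
    r = np.array([[logit]])
    for layer, rule, a in zip(reversed(model.layers), reversed(rules.layer_rules),
                              reversed(acts)):
        r = _propagate_layer(layer, rule, r, a, rules, absorbed)
    data = r[0, 0]
    if not np.all(np.isfinite(data)):
        raise FloatingPointError("non-finite relevance produced")
    meta = {
        "yhat": yhat,
        "logit": logit,
        "rules": list(rules.layer_rules),
        "epsilon": rules.epsilon,
        "alpha": rules.alpha,
        "beta": rules.beta,
        "fold_id": model.fold_id,
        "input_id": input_id,
        "absorbed": absorbed[0],
    }
    return ExplainResult(map=RelevanceMap(data=data, meta=meta), logit=logit, yhat=yhat)


def ensemble_explain(
    models: list[ClassifierModel],
    volume: np.ndarray,
    rules: RuleAssignment | str = "composite",
    input_id: str | None = None,
) -> ExplainResult:
    """Average the predictions and the voxel-wise relevance across models."""
    if len(models) == 0:
        raise ValueError("need at least one model")
    grids = {m.config.get("grid") for m in models}
    if len(grids) > 1:
        raise ValueError(f"models disagree on grid: {grids}")
    results = [explain(m, volume, rules=rules, input_id=input_id) for m in models]
    data = np.mean([res.map.data for res in results], axis=0)
    yhat = float(np.mean([res.yhat for res in results]))
    logit = float(np.mean([res.logit for res in results]))
    meta = dict(results[0].map.meta)
    meta.update({"yhat": yhat, "logit": logit, "fold_id": None,
                 "ensemble_size": len(models),
                 "absorbed": float(np.sum([r.map.meta["absorbed"] for r in results]))})
    return ExplainResult(map=RelevanceMap(data=data, meta=meta), logit=logit, yhat=yhat)
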