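"""Independent brute-force reference implementations used as test oracles.

Everything here works on explicitly materialized contribution matrices and
python loops — deliberately naive, sharing no code path with the package —
so agreement between the two routes is meaningful.
"""

import numpy as np


# ---------------------------------------------------------------------------
# naive relevance rules on an explicit (m -> n) weight matrix


def safe_div(r, z):
    out = np.zeros_like(r, dtype=float)
    nz = z != 0
    out[nz] = r[nz] / z[nz]
    return out


def naive_generic(W, b, a, r, eps=0.0):
    """r_m = sum_n C_mn / (eps-stabilized column sum) * r_n, C = a_m * W_mn."""
    C = a[:, None] * W
    z = C.sum(axis=0) + (b if b is not None else 0.0)
    if eps != 0.0:
        z = z + eps * np.where(z >= 0, 1.0, -1.0)
    return C @ safe_div(r, z)


def naive_alphabeta(W, b, a, r, alpha=1.0, beta=0.0):
    C = a[:, None] * W
    Cp = np.clip(C, 0, None)
    Cn = np.clip(C, None, 0)
    bp = np.clip(b, 0, None) if b is not None else 0.0
    bn = np.clip(b, None, 0) if b is not None else 0.0
    zp = Cp.sum(axis=0) + bp
    zn = Cn.sum(axis=0) + bn
    return alpha * (Cp @ safe_div(r, zp)) - beta * (Cn @ safe_div(r, zn))


def naive_flat(S, r):
    """S: binary (m, n) structural connectivity; uniform split per column."""
    counts = S.sum(axis=0).astype(float)
    return S @ safe_div(r, counts)


# ---------------------------------------------------------------------------
# whole-network naive LRP on flat vectors


def naive_forward(steps, x):
    """steps: list of ("linear", W, b) or ("relu",). Returns per-step inputs."""
    acts = []
    h = np.asarray(x, dtype=float)
    for step in steps:
        acts.append(h)
        if step[0] == "linear":
            _, W, b = step
            h = h @ W + (b if b is not None else 0.0)
        elif step[0] == "relu":
            h = np.maximum(h, 0)
        else:
            raise ValueError(step[0])
    return acts, h


def naive_lrp(steps, x, rules, r_out=None, eps=0.0, alpha=1.0, beta=0.0,
              structures=None):
    """Backward pass with a rule per step ('pass' for relu).

    ``structures`` optionally maps step index -> binary connectivity matrix
    for flat-rule steps (defaults to ones, i.e. dense connectivity).
    """
    acts, out = naive_forward(steps, x)
    r = np.atleast_1d(out.astype(float)).copy() if r_out is None else np.atleast_1d(
        np.asarray(r_out, dtype=float)
    )
    for i in reversed(range(len(steps))):
        step, a = steps[i], acts[i]
        rule = rules[i]
        if step[0] == "relu" or rule == "pass":
            continue
        _, W, b = step
        if rule == "generic":
            r = naive_generic(W, b, a, r, eps=0.0)
        elif rule == "epsilon":
            r = naive_generic(W, b, a, r, eps=eps)
        elif rule == "alphabeta":
            r = naive_alphabeta(W, b, a, r, alpha=alpha, beta=beta)
        elif rule == "flat":
            S = structures[i] if structures and i in structures else np.ones_like(W)
            r = naive_flat(S, r)
        else:
            raise ValueError(rule)
    return r, out


# ---------------------------------------------------------------------------
# conv as an explicit matrix (1 input channel, same zero padding, loops)


def conv_as_matrix(kernel, shape, n_out=1):
    """Materialize a same-padded 3D conv as (in_vox, out_vox) matrices.

    kernel: (n_out, k, k, k) single-input-channel weights.  Returns
    (weight_matrix, structure_matrix); columns indexed by (out_channel, voxel)
    in C order, structure marks in-bounds kernel taps (padding excluded).
    """
    kernel = np.asarray(kernel, dtype=float)
    if kernel.ndim == 3:
        kernel = kernel[None]
    k = kernel.shape[-1]
    half = k // 2
    nv = int(np.prod(shape))
    W = np.zeros((nv, n_out * nv))
    S = np.zeros((nv, n_out * nv))
    for o in range(n_out):
        for zi in range(shape[0]):
            for yi in range(shape[1]):
                for xi in range(shape[2]):
                    col = o * nv + np.ravel_multi_index((zi, yi, xi), shape)
                    for dz in range(-half, half + 1):
                        for dy in range(-half, half + 1):
                            for dx in range(-half, half + 1):
                                z, y, x = zi + dz, yi + dy, xi + dx
                                if not (0 <= z < shape[0] and 0 <= y < shape[1]
                                        and 0 <= x < shape[2]):
                                    continue
                                row = np.ravel_multi_index((z, y, x), shape)
                                W[row, col] = kernel[o, dz + half, dy + half, dx + half]
                                S[row, col] = 1.0
    return W, S


# ---------------------------------------------------------------------------
# misc voxel-loop oracles


def loop_dice(a, b):
    inter = both = 0.0
    for x, y in zip(np.ravel(a), np.ravel(b)):
        inter += x * y
        both += x + y
    return 0.0 if both == 0 else inter / both


def loop_ncc(a, b):
    x = np.ravel(a).astype(float)
    y = np.ravel(b).astype(float)
    xm, ym = x.mean(), y.mean()
    num = sum((xi - xm) * (yi - ym) for xi, yi in zip(x, y))
    den = np.sqrt(sum((xi - xm) ** 2 for xi in x) * sum((yi - ym) ** 2 for yi in y))
    return num / den


def loop_region_stats(data, labels, stat):
    out = {}
    for rid in sorted(set(labels.ravel().tolist()) - {0}):
        vals = [v for v, l in zip(data.ravel(), labels.ravel()) if l == rid]
        out[rid] = {"mean": np.mean, "sum": np.sum, "max": np.max}[stat](vals)
    return out
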