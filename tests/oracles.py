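"""Independent reference implementations used as test oracles.

Everything here is written as plainly as possible (explicit Python loops
over pixels, channels and experts, scalar arithmetic) and never calls the
package's vectorized/compiled code paths, so agreement is meaningful.
"""

from __future__ import annotations

import math

import numpy as np


def conv2d_loops(x: np.ndarray, w: np.ndarray, b: np.ndarray | None, padding: int) -> np.ndarray:
    """Direct convolution by quadruple loop. x: (B,C,H,W), w: (O,C,kh,kw)."""
    B, C, H, W = x.shape
    O, _, kh, kw = w.shape
    p = padding
    xp = np.zeros((B, C, H + 2 * p, W + 2 * p), dtype=np.float64)
    xp[:, :, p : p + H, p : p + W] = x
    Ho, Wo = H + 2 * p - kh + 1, W + 2 * p - kw + 1
    out = np.zeros((B, O, Ho, Wo), dtype=np.float64)
    for bb in range(B):
        for o in range(O):
            for y in range(Ho):
                for xx in range(Wo):
                    s = 0.0
                    for c in range(C):
                        for i in range(kh):
                            for j in range(kw):
                                s += w[o, c, i, j] * xp[bb, c, y + i, xx + j]
                    out[bb, o, y, xx] = s + (b[o] if b is not None else 0.0)
    return out


def softmax_1d(v: np.ndarray) -> np.ndarray:
    e = np.exp(v - v.max())
    return e / e.sum()


def mhmoe_loops(
    x: np.ndarray,
    expert_outputs: list[list[np.ndarray]],
    gate_weights: list[np.ndarray],
    num_heads: int,
) -> np.ndarray:
    """Fuse precomputed expert outputs with gate weights, pixel by pixel.

    expert_outputs[i][j]: (B, Ch, H, W) output of expert j on head i;
    gate_weights[i]: (B, k, H, W).  Heads are concatenated in order.
    """
    B, C, H, W = x.shape
    ch = C // num_heads
    out = np.zeros((B, C, H, W), dtype=np.float64)
    for i in range(num_heads):
        k = gate_weights[i].shape[1]
        for bb in range(B):
            for c in range(ch):
                for y in range(H):
                    for xx in range(W):
                        s = 0.0
                        for j in range(k):
                            s += gate_weights[i][bb, j, y, xx] * expert_outputs[i][j][bb, c, y, xx]
                        out[bb, i * ch + c, y, xx] = s
    return out


def attention_1head_loops(tokens: np.ndarray, wq, wk, wv, wout, bout, scale: float) -> np.ndarray:
    """Single-head self-attention on (N, C) tokens with scalar loops."""
    N, C = tokens.shape
    q = tokens @ wq
    k = tokens @ wk
    v = tokens @ wv
    out_ctx = np.zeros_like(v)
    for a in range(N):
        logits = np.array([scale * float(q[a] @ k[b]) for b in range(N)])
        weights = softmax_1d(logits)
        out_ctx[a] = sum(weights[b] * v[b] for b in range(N))
    return out_ctx @ wout + bout


def mpa_effective_kernel(K: np.ndarray, m_learn: np.ndarray, theta: float) -> np.ndarray:
    """Masked kernel K*M with M_n = 1 - theta * m_learn * c_mask * sum(K_n)."""
    O, C, kh, kw = K.shape
    c_mask = np.full((kh, kw), 0.5)
    c_mask[kh // 2, kw // 2] = 1.0
    keff = np.zeros_like(K, dtype=np.float64)
    for o in range(O):
        s = K[o].sum()
        M = 1.0 - theta * m_learn * c_mask * s
        keff[o] = K[o] * M
    return keff


def region_interaction_script(
    quads: list[np.ndarray], w1, b1, w2, b2
) -> list[np.ndarray]:
    """Scripted operator chain for the cross-quadrant interaction.

    quads: four (B,C,h,w) arrays; w1/b1: conv over channel-concatenated
    regions (4C -> 4C); w2/b2: conv over the reassembled full-size map
    (C -> C).  Returns the four updated regions.
    """
    B, C, h, w = quads[0].shape
    cat = np.concatenate(quads, axis=1)
    mixed = np.maximum(conv2d_loops(cat, w1, b1, padding=1), 0.0)
    parts = [mixed[:, i * C : (i + 1) * C] for i in range(4)]
    top = np.concatenate([parts[0], parts[1]], axis=3)
    bottom = np.concatenate([parts[2], parts[3]], axis=3)
    full = np.concatenate([top, bottom], axis=2)
    fa_full = 1.0 / (1.0 + np.exp(-conv2d_loops(full, w2, b2, padding=1)))
    fa_quads = [
        fa_full[:, :, :h, :w],
        fa_full[:, :, :h, w:],
        fa_full[:, :, h:, :w],
        fa_full[:, :, h:, w:],
    ]
    out = []
    for f, fa in zip(quads, fa_quads):
        z = f + f * fa
        soft = np.zeros_like(z)
        for bb in range(B):
            for y in range(h):
                for xx in range(w):
                    soft[bb, :, y, xx] = softmax_1d(z[bb, :, y, xx])
        out.append(soft)
    return out


def task_loss_loops(logits: np.ndarray, target: np.ndarray, eps: float = 1e-5) -> tuple[float, float]:
    """(mean CE, summed foreground soft-Dice loss) by per-pixel loops.

    logits: (B,K,H,W); target: (B,H,W) class indices in {0..K-1}.
    """
    B, K, H, W = logits.shape
    probs = np.zeros_like(logits, dtype=np.float64)
    ce = 0.0
    for bb in range(B):
        for y in range(H):
            for xx in range(W):
                p = softmax_1d(logits[bb, :, y, xx].astype(np.float64))
                probs[bb, :, y, xx] = p
                ce -= math.log(p[target[bb, y, xx]])
    ce /= B * H * W
    dice_total = 0.0
    for c in (1, 2, 3):
        per_sample = []
        for bb in range(B):
            inter = denom = 0.0
            for y in range(H):
                for xx in range(W):
                    t = 1.0 if target[bb, y, xx] == c else 0.0
                    inter += probs[bb, c, y, xx] * t
                    denom += probs[bb, c, y, xx] + t
            per_sample.append(1.0 - (2.0 * inter + eps) / (denom + eps))
        dice_total += float(np.mean(per_sample))
    return ce, dice_total


def kd_loss_scalar(zt: np.ndarray, zs: np.ndarray, tau: float) -> float:
    """Squared distance of temperature-softened softmaxes for one pixel."""
    return float(np.sum((softmax_1d(zt / tau) - softmax_1d(zs / tau)) ** 2))
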