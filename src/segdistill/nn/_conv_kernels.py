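"""Direct 2-D convolution kernels (forward, input-grad, weight-grad).

Compiled with numba for single-core throughput: direct accumulation over
kernel taps keeps memory traffic far below an im2col formulation at the
small channel counts these networks use.  All arrays are float32; inputs
are pre-padded by the caller.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["conv_forward", "conv_backward_input", "conv_backward_weight"]


@njit(cache=True, fastmath=True)
def conv_forward(xp: np.ndarray, w: np.ndarray) -> np.ndarray:
    """xp: (B, C, Hp, Wp) padded input; w: (O, C, kh, kw) -> (B, O, H, W)."""
    B, C, Hp, Wp = xp.shape
    O, _, kh, kw = w.shape
    H = Hp - kh + 1
    W = Wp - kw + 1
    out = np.zeros((B, O, H, W), dtype=np.float32)
    for b in range(B):
        for o in range(O):
            acc = out[b, o]
            for c in range(C):
                xc = xp[b, c]
                for i in range(kh):
                    for j in range(kw):
                        wv = w[o, c, i, j]
                        for y in range(H):
                            xrow = xc[y + i]
                            arow = acc[y]
                            for x in range(W):
                                arow[x] += wv * xrow[x + j]
    return out


@njit(cache=True, fastmath=True)
def conv_backward_input(dout: np.ndarray, w: np.ndarray, Hp: int, Wp: int) -> np.ndarray:
    """dout: (B, O, H, W); w: (O, C, kh, kw) -> gradient wrt padded input."""
    B, O, H, W = dout.shape
    _, C, kh, kw = w.shape
    dxp = np.zeros((B, C, Hp, Wp), dtype=np.float32)
    for b in range(B):
        for o in range(O):
            g = dout[b, o]
            for c in range(C):
                dxc = dxp[b, c]
                for i in range(kh):
                    for j in range(kw):
                        wv = w[o, c, i, j]
                        for y in range(H):
                            grow = g[y]
                            drow = dxc[y + i]
                            for x in range(W):
                                drow[x + j] += wv * grow[x]
    return dxp


@njit(cache=True, fastmath=True)
def conv_backward_weight(dout: np.ndarray, xp: np.ndarray, kh: int, kw: int) -> np.ndarray:
    """dout: (B, O, H, W); xp: (B, C, Hp, Wp) -> gradient wrt weights."""
    B, O, H, W = dout.shape
    _, C, _, _ = xp.shape
    dw = np.zeros((O, C, kh, kw), dtype=np.float32)
    for b in range(B):
        for o in range(O):
            g = dout[b, o]
            for c in range(C):
                xc = xp[b, c]
                for i in range(kh):
                    for j in range(kw):
                        s = np.float32(0.0)
                        for y in range(H):
                            grow = g[y]
                            xrow = xc[y + i]
                            for x in range(W):
                                s += grow[x] * xrow[x + j]
                        dw[o, c, i, j] += s
    return dw
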